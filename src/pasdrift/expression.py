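"""Expression-matrix and annotation I/O, and age-group assignment.

The pipeline consumes *already normalized*, linear-scale expression matrices
(genes x samples) — one per dataset — plus a sample annotation table giving
each sample's dataset, disease condition, donor age and (optionally) culture
passage number.  Samples from healthy donors are binned by age into the
"Young" (15-30 y), "Middle" (40-55 y) and "Old" (60+ y) fibroblast groups;
progeria (HGPS) samples form their own group regardless of age.  Ages that
fall in the gaps between the closed bins (0-14, 31-39, 56-59) are excluded
rather than rounded into a neighbouring group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EPS_EXPR",
    "AGE_BINS",
    "ExpressionMatrix",
    "SampleAnnotation",
    "read_expression_matrix",
    "read_annotations",
    "write_annotations",
    "assign_age_group",
    "assemble_groups",
]

logger = logging.getLogger(__name__)

#: Floor for non-positive normalized intensities so ratios and logs are defined.
EPS_EXPR = 1e-6

#: Closed age intervals (years) defining the healthy-donor groups.
AGE_BINS: Mapping[str, tuple[float, float]] = {
    "Young": (15, 30),
    "Middle": (40, 55),
    "Old": (60, float("inf")),
}

GROUP_LABELS = ("Young", "Middle", "Old", "HGPS")


@dataclass
class ExpressionMatrix:
    """Linear-scale gene x sample intensities for one dataset.

    ``values`` is a DataFrame indexed by gene symbol with sample-id columns;
    all entries are finite and >= :data:`EPS_EXPR` after floor correction.
    """

    values: pd.DataFrame
    dataset_id: str

    def __post_init__(self) -> None:
        v = self.values
        if v.empty:
            raise ValueError(f"dataset {self.dataset_id!r}: empty expression matrix")
        if v.index.has_duplicates:
            raise ValueError(f"dataset {self.dataset_id!r}: duplicate gene ids")
        if v.columns.has_duplicates:
            raise ValueError(f"dataset {self.dataset_id!r}: duplicate sample ids")
        arr = v.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"dataset {self.dataset_id!r}: non-finite expression values")
        if (arr < EPS_EXPR).any():
            raise ValueError(
                f"dataset {self.dataset_id!r}: values below the {EPS_EXPR} floor; "
                "use read_expression_matrix which applies floor correction"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample metadata used for grouping and reference selection."""

    sample_id: str
    dataset_id: str
    condition: Literal["normal", "HGPS"]
    age: float | None = None
    passage: int | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("normal", "HGPS"):
            raise ValueError(f"{self.sample_id}: unknown condition {self.condition!r}")
        if self.age is not None and self.age < 0:
            raise ValueError(f"{self.sample_id}: negative age")
        if self.passage is not None and self.passage <= 0:
            raise ValueError(f"{self.sample_id}: passage must be a positive integer")


def _collapse_duplicates(df: pd.DataFrame, how: Literal["max", "mean"]) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    grouped = df.groupby(level=0, sort=False)
    return grouped.max() if how == "max" else grouped.mean()


def read_expression_matrix(
    path: str | Path,
    dataset_id: str | None = None,
    dialect: Literal["tsv", "gct"] = "tsv",
    log2_input: bool = False,
    duplicate_genes: Literal["max", "mean"] = "max",
) -> ExpressionMatrix:
    """Read a gene x sample expression matrix.

    Parameters
    ----------
    dialect
        ``tsv``: header row of sample ids, first column named ``gene``.
        ``gct``: GCT 1.2 (two header lines, then Name/Description columns).
    log2_input
        If True the file stores log2 intensities; they are un-logged (2**x)
        on read so downstream ratios operate on the linear scale.
    duplicate_genes
        Duplicate gene rows (multiple probes) are collapsed by per-gene
        maximum by default, or by mean.

    Non-positive entries are floored to :data:`EPS_EXPR`.
    """
    path = Path(path)
    if dialect == "gct":
        with path.open() as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ValueError(f"{path}: expected GCT 1.2, got header {version!r}")
            fh.readline()  # dimensions line; pandas infers shapes itself
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=df.columns[0])  # Description column
    elif dialect == "tsv":
        with path.open() as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            raise ValueError(f"{path}: duplicate sample ids in header")
        df = pd.read_csv(path, sep="\t", index_col=0)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no data rows/columns")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids in header")
    if df.isna().to_numpy().any():
        raise ValueError(f"{path}: ragged rows or missing values")
    df.index = df.index.astype(str)
    df = df.astype(float)
    if log2_input:
        df = np.power(2.0, df)
    df = _collapse_duplicates(df, duplicate_genes)
    n_floored = int((df.to_numpy() < EPS_EXPR).sum())
    if n_floored:
        logger.info("%s: floored %d non-positive entries to %g", path, n_floored, EPS_EXPR)
    df = df.clip(lower=EPS_EXPR)
    return ExpressionMatrix(values=df, dataset_id=dataset_id or path.stem)


_ANNOT_COLS = ["sample_id", "dataset_id", "condition", "age", "passage"]


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read the annotation TSV (columns sample_id, dataset_id, condition, age, passage)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "dataset_id": str})
    missing = set(_ANNOT_COLS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        age = getattr(row, "age", None)
        passage = getattr(row, "passage", None)
        out.append(
            SampleAnnotation(
                sample_id=str(row.sample_id),
                dataset_id=str(row.dataset_id),
                condition=str(row.condition),
                age=None if age is None or pd.isna(age) else float(age),
                passage=None if passage is None or pd.isna(passage) else int(passage),
            )
        )
    return out


def write_annotations(annotations: Iterable[SampleAnnotation], path: str | Path) -> None:
    rows = [
        {
            "sample_id": a.sample_id,
            "dataset_id": a.dataset_id,
            "condition": a.condition,
            "age": "" if a.age is None else a.age,
            "passage": "" if a.passage is None else a.passage,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_ANNOT_COLS).to_csv(path, sep="\t", index=False)


def assign_age_group(annotation: SampleAnnotation) -> str:
    """Map a sample to Young / Middle / Old / HGPS / excluded.

    HGPS condition wins regardless of age.  Healthy donors are binned by the
    closed intervals in :data:`AGE_BINS`; ages in the gaps are ``excluded``.
    A healthy sample with no recorded age cannot be binned and is an error.
    """
    if annotation.condition == "HGPS":
        return "HGPS"
    if annotation.age is None:
        raise ValueError(f"{annotation.sample_id}: healthy sample without donor age")
    for label, (lo, hi) in AGE_BINS.items():
        if lo <= annotation.age <= hi:
            return label
    return "excluded"


def assemble_groups(
    annotations: Iterable[SampleAnnotation],
    matrices: Mapping[str, ExpressionMatrix],
) -> dict[str, list[tuple[str, str]]]:
    """Pool annotated samples into groups across datasets.

    Returns ``{group: [(dataset_id, sample_id), ...]}`` including an
    ``"excluded"`` entry.  Every annotated sample must appear in exactly one
    matrix; sample conservation |assigned| + |excluded| = |annotated| holds
    by construction.
    """
    groups: dict[str, list[tuple[str, str]]] = {g: [] for g in GROUP_LABELS}
    groups["excluded"] = []
    for a in annotations:
        hits = [
            d for d, m in matrices.items() if a.sample_id in m.values.columns
        ]
        if not hits:
            raise ValueError(f"sample {a.sample_id!r} absent from all expression matrices")
        if len(hits) > 1:
            raise ValueError(f"sample {a.sample_id!r} present in multiple matrices: {hits}")
        if hits[0] != a.dataset_id:
            raise ValueError(
                f"sample {a.sample_id!r} annotated in dataset {a.dataset_id!r} "
                f"but found in {hits[0]!r}"
            )
        label = assign_age_group(a)
        groups[label].append((a.dataset_id, a.sample_id))
    if groups["excluded"]:
        logger.info(
            "excluded %d samples outside the age bins: %s",
            len(groups["excluded"]),
            [s for _, s in groups["excluded"]],
        )
    if all(not groups[g] for g in GROUP_LABELS):
        warnings.warn("all samples were excluded from the age/condition groups")
    return groups
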