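"""Pathway Activation Strength (PAS) scoring.

For every case sample the engine compares gene expression against a
within-dataset reference group and aggregates the changes over each
pathway's member genes:

    PAS_p(sample) = sum over genes n in p of  ARR_n * BTIF_n * lg(CNR_n)

where ``CNR_n`` (case-to-normal ratio) is the sample's linear-scale
expression of gene n divided by the reference-group mean, ``lg`` is log10,
``ARR_n`` is the gene's activator/repressor coefficient in pathway p, and
``BTIF_n`` is a 0/1 significance gate.  Positive PAS means pathway
up-regulation, negative means down-regulation.

The gate is decided once per (dataset, case group): a two-sided pooled
Student's t-test on log2 values against the reference group, Benjamini-
Hochberg FDR adjustment across all genes, and a linear-scale group fold
change.  In *filtered* mode a gene contributes only when
max(FC, 1/FC) >= 1.5 and q < 0.05 (defaults; configurable); in
*unfiltered* mode every gene contributes.  A reference group scored
against its own mean in filtered mode therefore yields exactly zero PAS
everywhere, which is why reference-group samples are, by default, scored
unfiltered so their within-group variation is retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .pathways import PathwayCollection, PathwayDefinition

__all__ = [
    "DifferentialSummary",
    "PASMatrix",
    "compute_cnr",
    "test_differential",
    "compute_btif",
    "compute_pas",
    "compute_pas_matrix",
]

logger = logging.getLogger(__name__)

Mode = Literal["filtered", "unfiltered"]


@dataclass
class DifferentialSummary:
    """Group-level differential-expression summary for one (dataset, case group).

    ``table`` has one row per gene with columns ``fc`` (linear-scale ratio of
    case group mean to reference mean), ``p`` (two-sided pooled t-test on
    log2 values), ``q`` (BH-adjusted p) and ``btif`` (0/1 gate).
    ``cnr`` holds the per-sample case-to-normal ratios (genes x case samples).
    """

    dataset_id: str
    group: str
    mode: Mode
    table: pd.DataFrame
    cnr: pd.DataFrame


@dataclass
class PASMatrix:
    """Pathway x sample activation scores with sample group/dataset labels."""

    values: pd.DataFrame
    sample_groups: pd.Series
    sample_datasets: pd.Series
    mode: Mode
    reference: dict[str, list[str]] = field(default_factory=dict)
    differentials: list[DifferentialSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.sample_groups.index):
            self.sample_groups = self.sample_groups.reindex(self.values.columns)
        if not self.values.columns.equals(self.sample_datasets.index):
            self.sample_datasets = self.sample_datasets.reindex(self.values.columns)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.values.index)

    def group_values(self, pathway_id: str, group: str) -> np.ndarray:
        """Finite PAS values of one pathway for all samples of ``group``."""
        cols = self.sample_groups.index[self.sample_groups == group]
        vals = self.values.loc[pathway_id, cols].to_numpy(dtype=float)
        return vals[np.isfinite(vals)]


def compute_cnr(
    case_sample: pd.Series,
    reference: pd.DataFrame,
    ref_average: Literal["arithmetic", "geometric"] = "arithmetic",
) -> pd.Series:
    """Case-to-normal ratio per gene: case value / reference-group mean.

    Genes absent from the reference are dropped with a warning.  The
    reference mean is arithmetic on the linear scale by default (geometric
    available).  All inputs must be positive, so the result is positive.
    """
    shared = case_sample.index.intersection(reference.index)
    missing = case_sample.index.difference(reference.index)
    if len(missing):
        warnings.warn(
            f"{len(missing)} genes absent from the reference were dropped "
            f"(e.g. {list(missing[:3])})"
        )
    ref = reference.loc[shared]
    if ref_average == "arithmetic":
        denom = ref.mean(axis=1)
    elif ref_average == "geometric":
        denom = np.exp(np.log(ref).mean(axis=1))
    else:
        raise ValueError(f"unknown ref_average {ref_average!r}")
    cnr = case_sample.loc[shared] / denom
    if (cnr <= 0).any() or not np.isfinite(cnr.to_numpy()).all():
        raise ValueError("CNR must be strictly positive and finite")
    return cnr


def _pooled_t(case_log: np.ndarray, ref_log: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided pooled-variance Student's t-test per gene (rows)."""
    n1, n2 = case_log.shape[1], ref_log.shape[1]
    df = n1 + n2 - 2
    m1, m2 = case_log.mean(axis=1), ref_log.mean(axis=1)
    v1 = case_log.var(axis=1, ddof=1)
    v2 = ref_log.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # degenerate genes: zero pooled variance
    zero = se == 0
    t[zero & (diff == 0)] = 0.0
    t[zero & (diff != 0)] = np.inf * np.sign(diff[zero & (diff != 0)])
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[zero & (diff == 0)] = 1.0
    p[np.isinf(t)] = 0.0
    return t, p


def test_differential(
    case_matrix: pd.DataFrame, reference_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene (FC, p, q) for a case group versus a reference group.

    The t-test runs on log2-transformed values with pooled variance; p-values
    are BH-FDR adjusted across all tested genes; the fold change is the ratio
    of linear-scale group means.  With fewer than two samples on either side
    no test is possible and all p are set to 1 with a warning.
    """
    shared = case_matrix.index.intersection(reference_matrix.index)
    if len(shared) == 0:
        raise ValueError("case and reference matrices share no genes")
    case = case_matrix.loc[shared].to_numpy(dtype=float)
    ref = reference_matrix.loc[shared].to_numpy(dtype=float)
    fc = case.mean(axis=1) / ref.mean(axis=1)
    if case.shape[1] < 2 or ref.shape[1] < 2:
        warnings.warn(
            "fewer than 2 samples in case or reference group; "
            "p-values set to 1 (no test possible)"
        )
        p = np.ones(len(shared))
    else:
        _, p = _pooled_t(np.log2(case), np.log2(ref))
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"fc": fc, "p": p, "q": q}, index=shared)


def compute_btif(
    fc: pd.Series,
    q: pd.Series,
    mode: Mode,
    fc_threshold: float = 1.5,
    fdr: float = 0.05,
) -> pd.Series:
    """0/1 significance gate per gene.

    Filtered mode: gene passes iff max(FC, 1/FC) >= ``fc_threshold`` and
    q < ``fdr``.  Unfiltered mode: every gene passes.
    """
    if mode == "unfiltered":
        return pd.Series(1, index=fc.index, dtype=int)
    if mode != "filtered":
        raise ValueError(f"unknown mode {mode!r}")
    fold = np.maximum(fc, 1.0 / fc)
    return ((fold >= fc_threshold) & (q < fdr)).astype(int)


def compute_pas(
    pathway: PathwayDefinition,
    cnr: pd.Series,
    btif: pd.Series,
) -> float:
    """PAS for one sample and one pathway: sum of ARR * BTIF * log10(CNR).

    Member genes missing from ``cnr`` contribute 0 (with a warning); a
    pathway with no member gene present has no defined score and returns NaN.
    """
    present = [g for g in pathway.gene_roles if g in cnr.index]
    if not present:
        warnings.warn(
            f"pathway {pathway.pathway_id!r}: no member gene present; PAS undefined"
        )
        return float("nan")
    if len(present) < len(pathway.gene_roles):
        warnings.warn(
            f"pathway {pathway.pathway_id!r}: "
            f"{len(pathway.gene_roles) - len(present)} member genes missing; "
            "they contribute 0"
        )
    arr = np.array([pathway.gene_roles[g] for g in present])
    b = btif.loc[present].to_numpy(dtype=float)
    lg = np.log10(cnr.loc[present].to_numpy(dtype=float))
    return float(np.sum(arr * b * lg))


def _pathway_weights(
    collection: PathwayCollection, genes: pd.Index
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Pre-resolve, per pathway, the row positions and ARR weights of member genes."""
    pos = {g: i for i, g in enumerate(genes)}
    idx_list, w_list, n_present = [], [], []
    for p in collection:
        members = [(pos[g], c) for g, c in p.gene_roles.items() if g in pos]
        idx_list.append(np.array([i for i, _ in members], dtype=int))
        w_list.append(np.array([c for _, c in members], dtype=float))
        n_present.append(len(members))
    return np.array(n_present), idx_list, w_list


def compute_pas_matrix(
    matrices: Mapping[str, ExpressionMatrix],
    groups: Mapping[str, Sequence[tuple[str, str]]],
    collection: PathwayCollection,
    reference: Mapping[str, Sequence[str]],
    mode: Mode = "filtered",
    self_reference_mode: Mode = "unfiltered",
    fc_threshold: float = 1.5,
    fdr: float = 0.05,
    ref_average: Literal["arithmetic", "geometric"] = "arithmetic",
) -> PASMatrix:
    """Score every grouped sample of every dataset against its dataset reference.

    Parameters
    ----------
    matrices
        ``dataset_id -> ExpressionMatrix``; each dataset is processed
        separately against its own reference samples.
    groups
        ``group label -> [(dataset_id, sample_id), ...]`` as produced by
        :func:`pasdrift.expression.assemble_groups` (an ``"excluded"`` entry
        is ignored).
    reference
        ``dataset_id -> reference sample ids`` within that dataset.
    mode
        Gate mode for case groups (``filtered`` by default).
    self_reference_mode
        Gate mode applied when a group *is* its dataset's reference
        (e.g. the Young group scored against its own mean).  ``unfiltered``
        by default, so within-reference variation yields non-zero scores;
        with ``filtered`` such samples score exactly 0 everywhere.

    The gate (t-test + BH + fold change) is computed once per
    (dataset, case group) and shared by that group's samples, while CNR is
    per sample.  Columns from all datasets are concatenated.
    """
    for ds in {d for g in groups.values() for d, _ in g}:
        if ds not in matrices:
            raise ValueError(f"group sample references unknown dataset {ds!r}")
    columns: list[str] = []
    col_group: dict[str, str] = {}
    col_dataset: dict[str, str] = {}
    col_pas: dict[str, np.ndarray] = {}
    diffs: list[DifferentialSummary] = []

    pathway_ids = collection.pathway_ids
    for ds_id, em in matrices.items():
        if ds_id not in reference:
            raise ValueError(f"dataset {ds_id!r} has no designated reference samples")
        ref_samples = list(reference[ds_id])
        missing_ref = [s for s in ref_samples if s not in em.values.columns]
        if missing_ref or not ref_samples:
            raise ValueError(
                f"dataset {ds_id!r}: reference samples missing from matrix: {missing_ref}"
            )
        ref_matrix = em.values[ref_samples]
        if ref_average == "arithmetic":
            ref_mean = ref_matrix.mean(axis=1)
        else:
            ref_mean = np.exp(np.log(ref_matrix).mean(axis=1))
        n_present, idx_list, w_list = _pathway_weights(collection, em.values.index)

        for group_label, members in groups.items():
            if group_label == "excluded":
                continue
            case_samples = [s for d, s in members if d == ds_id]
            if not case_samples:
                continue
            group_mode = (
                self_reference_mode if set(case_samples) == set(ref_samples) else mode
            )
            if group_mode == "filtered":
                table = test_differential(em.values[case_samples], ref_matrix)
                table["btif"] = compute_btif(
                    table["fc"], table["q"], "filtered", fc_threshold, fdr
                )
            else:
                table = pd.DataFrame(
                    {
                        "fc": em.values[case_samples].mean(axis=1) / ref_mean,
                        "p": 1.0,
                        "q": 1.0,
                        "btif": 1,
                    },
                    index=em.values.index,
                )
            btif = table["btif"].reindex(em.values.index).fillna(0).to_numpy(dtype=float)
            # per-sample CNR on the linear scale, vectorized over genes
            cnr = em.values[case_samples].div(ref_mean, axis=0)
            diffs.append(
                DifferentialSummary(
                    dataset_id=ds_id,
                    group=group_label,
                    mode=group_mode,
                    table=table,
                    cnr=cnr,
                )
            )
            lg = np.log10(cnr.to_numpy(dtype=float))
            weighted = lg * btif[:, None]
            for s_pos, sample in enumerate(case_samples):
                scores = np.empty(len(pathway_ids))
                for k in range(len(pathway_ids)):
                    if n_present[k] == 0:
                        scores[k] = np.nan
                    else:
                        scores[k] = float(
                            np.dot(w_list[k], weighted[idx_list[k], s_pos])
                        )
                col_pas[sample] = scores
                col_group[sample] = group_label
                col_dataset[sample] = ds_id
                columns.append(sample)
        absent = [
            pathway_ids[k] for k in range(len(pathway_ids)) if n_present[k] == 0
        ]
        if absent:
            logger.warning(
                "dataset %s: pathways with no member gene in the matrix "
                "(PAS reported missing): %s",
                ds_id,
                absent,
            )

    if not columns:
        raise ValueError("no grouped samples found in any dataset")
    values = pd.DataFrame(
        {s: col_pas[s] for s in columns}, index=pathway_ids, columns=columns
    )
    return PASMatrix(
        values=values,
        sample_groups=pd.Series(col_group, name="group").reindex(columns),
        sample_datasets=pd.Series(col_dataset, name="dataset").reindex(columns),
        mode=mode,
        reference={d: list(r) for d, r in reference.items()},
        differentials=diffs,
    )
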