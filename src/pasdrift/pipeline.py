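"""End-to-end orchestration: inputs -> PAS -> equivalence/Venn -> drift outputs.

`run_pipeline` drives the full analysis on either a synthetic preset or
on-disk inputs (expression TSVs + annotation table + pathway file) and
writes a reproducible result bundle: the PAS matrix with its sample-label
sidecar, per-(dataset, group) differential tables, the equivalence table,
the Venn/near-zero JSON, correlation/PCA/drift tables and a run manifest
echoing the configuration, package versions and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .drift import correlation_cluster, passage_drift, passage_group_means, pca_embed
from .equivalence import (
    EPSILON_MULTI,
    EPSILON_PAIR,
    near_zero_pathways,
    venn_similarity,
)
from .expression import assemble_groups, read_annotations, read_expression_matrix
from .pas import compute_pas_matrix
from .pathways import load_pathway_collection
from .synth import StudyBundle, make_paper_like_study

__all__ = ["PipelineConfig", "run_pipeline", "write_pas_outputs"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the pipeline with the study's defaults.

    Either ``preset`` (synthetic study) or the three input paths must be
    given.  ``reference_groups`` maps dataset id -> the group label serving
    as its reference; the special label ``"excluded"`` designates the
    dataset's unassigned samples (e.g. matched healthy controls).
    """

    out_dir: str = "results/run"
    preset: str | None = None
    expression_paths: dict[str, str] = field(default_factory=dict)
    annotation_path: str | None = None
    pathway_path: str | None = None
    reference_groups: dict[str, str] = field(default_factory=dict)
    mode: str = "filtered"
    fc_threshold: float = 1.5
    fdr: float = 0.05
    epsilon_pair: float = EPSILON_PAIR
    epsilon_multi: float = EPSILON_MULTI
    alpha: float = 0.05
    flat_threshold: float = 0.05
    near_zero_delta: float = 0.74
    log2_input: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        for name in ("fc_threshold", "fdr", "epsilon_pair", "epsilon_multi",
                     "flat_threshold", "near_zero_delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.preset is None and not (
            self.expression_paths and self.annotation_path and self.pathway_path
        ):
            raise ValueError("either a preset or full input paths are required")


def _load_inputs(config: PipelineConfig) -> StudyBundle:
    if config.preset is not None:
        return make_paper_like_study(config.preset, seed=config.seed)
    matrices = {
        ds: read_expression_matrix(path, dataset_id=ds, log2_input=config.log2_input)
        for ds, path in config.expression_paths.items()
    }
    annotations = read_annotations(config.annotation_path)
    collection = load_pathway_collection(config.pathway_path)
    groups = assemble_groups(annotations, matrices)
    reference: dict[str, list[str]] = {}
    for ds in matrices:
        label = config.reference_groups.get(ds)
        if label is None:
            raise ValueError(f"no reference group configured for dataset {ds!r}")
        pool = groups.get(label, [])
        reference[ds] = [s for d, s in pool if d == ds]
        if not reference[ds]:
            raise ValueError(f"dataset {ds!r}: reference group {label!r} empty")
    return StudyBundle(
        config=None,
        collection=collection,
        matrices=matrices,
        annotations=annotations,
        groups=groups,
        reference=reference,
        truth=None,
    )


def write_pas_outputs(pas, out_dir: Path) -> None:
    """PAS TSV + sample-label sidecar + per-(dataset, group) differential TSVs."""
    out_dir.mkdir(parents=True, exist_ok=True)
    pas.values.rename_axis("pathway_id").to_csv(out_dir / "pas.tsv", sep="\t")
    sidecar = pd.DataFrame(
        {"group": pas.sample_groups, "dataset": pas.sample_datasets}
    ).rename_axis("sample_id")
    sidecar.to_csv(out_dir / "sample_groups.tsv", sep="\t")
    diff_dir = out_dir / "differential"
    diff_dir.mkdir(exist_ok=True)
    for d in pas.differentials:
        d.table.rename_axis("gene").to_csv(
            diff_dir / f"{d.dataset_id}_{d.group}.tsv", sep="\t"
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a summary dict mirroring the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = _load_inputs(config)

    pas = compute_pas_matrix(
        bundle.matrices,
        bundle.groups,
        bundle.collection,
        bundle.reference,
        mode=config.mode,
        fc_threshold=config.fc_threshold,
        fdr=config.fdr,
    )
    write_pas_outputs(pas, out_dir)

    summary: dict = {"n_samples": int(pas.values.shape[1]),
                     "n_pathways": int(pas.values.shape[0])}

    group_sizes = pas.sample_groups.value_counts()
    multi_group = (group_sizes >= 2).sum() >= 2
    passage_study = all(g.startswith("p") and g[1:].isdigit() for g in group_sizes.index)

    if multi_group and not passage_study:
        venn = venn_similarity(
            pas,
            epsilon_pair=config.epsilon_pair,
            epsilon_multi=config.epsilon_multi,
            alpha=config.alpha,
        )
        near_zero = near_zero_pathways(pas, venn, delta=config.near_zero_delta)
        rows = [
            {
                "pathway_id": r.pathway_id,
                "comparison": "+".join(r.comparison),
                "kind": r.kind,
                "statistic": r.statistic,
                "critical_value": r.critical_value,
                "equivalent": r.equivalent,
                **{f"mean_{g}": m for g, m in r.mean_pas_per_group.items()},
            }
            for r in venn.results
        ]
        pd.DataFrame(rows).to_csv(out_dir / "equivalence.tsv", sep="\t", index=False)
        with (out_dir / "venn.json").open("w") as fh:
            json.dump(venn.to_json_dict(), fh, indent=1, sort_keys=True)
        summary["venn_region_counts"] = {
            "+".join(k): v for k, v in venn.region_counts().items()
        }
        summary["near_zero"] = sorted(near_zero)

        corr = correlation_cluster(pas)
        corr.correlations.rename_axis("sample_id").to_csv(
            out_dir / "correlation.tsv", sep="\t"
        )
        (out_dir / "leaf_order.txt").write_text("\n".join(corr.leaf_order) + "\n")
        emb = pca_embed(pas, n_components=3)
        coords = emb.coordinates.copy()
        coords["group"] = pas.sample_groups.reindex(coords.index)
        coords.rename_axis("sample_id").to_csv(out_dir / "pca.tsv", sep="\t")
        summary["pca_explained_variance"] = [
            float(v) for v in emb.explained_variance_ratio
        ]

    if passage_study:
        # trends are classified over the case passage groups; the reference
        # passage group anchors the scores at ~0 and is not part of the series
        ref_samples = {s for ss in pas.reference.values() for s in ss}
        case_groups = [
            g for g in group_sizes.index
            if not set(pas.sample_groups.index[pas.sample_groups == g]) <= ref_samples
        ]
        ordered = sorted(case_groups, key=lambda g: int(g[1:]))
        if len(ordered) < 3:
            ordered = sorted(group_sizes.index, key=lambda g: int(g[1:]))
        means = passage_group_means(pas, ordered)
        profile = passage_drift(means, flat_threshold=config.flat_threshold)
        drift_tab = profile.means.copy()
        drift_tab["trend"] = profile.labels
        drift_tab.rename_axis("pathway_id").to_csv(out_dir / "drift.tsv", sep="\t")
        summary["trend_counts"] = profile.labels.value_counts().to_dict()

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {
            "pasdrift": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "summary": summary,
    }
    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline finished: %s", summary)
    return manifest
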