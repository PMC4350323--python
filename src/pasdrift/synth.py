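"""Synthetic multi-dataset expression studies with known ground truth.

The generator emulates the statistical structure of pooled fibroblast
microarray studies so that every downstream stage (PAS scoring, equivalence
testing, drift summaries) can be validated against planted truth without
any external downloads:

* several independent datasets, each with its own reference group
  (the "Young" samples of an aging dataset, matched healthy controls of a
  progeria dataset, or low-passage cells of a senescence series);
* per-pathway coordinated regulation: a log2 effect applied to every member
  gene with sign multiplied by the gene's activator/repressor role, so a
  "+1 up-regulation" raises activators and lowers repressors and the
  resulting PAS sign is analytically predictable;
* multiplicative log-normal measurement noise (normal on the log2 scale)
  and dataset-level per-gene baseline offsets emulating platform pooling;
* annotations with donor ages drawn uniformly from each group's age range.

Two presets mirror the designs this package analyzes: ``aging4`` — four
groups (Young/Middle/Old/HGPS) of 15/25/16/26 samples spread over seven
pseudo-datasets, with 13 pathways planted equivalent across
{Middle, Old, HGPS}, 12 more across {Middle, HGPS}, 5 null pathways
equivalent-and-near-zero in all four groups and 35 pathways drifting with
distinct per-group magnitudes — and ``senescence`` — one dataset with
passage groups 30 (reference, 3 samples) / 50 (4) / 70 (3) / 80 (2) and
planted monotone, flat and non-monotonic passage trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import EPS_EXPR, ExpressionMatrix, SampleAnnotation, assemble_groups
from .pathways import PathwayCollection, PathwayDefinition

__all__ = [
    "SyntheticStudyConfig",
    "GroundTruth",
    "StudyBundle",
    "generate_pathway_collection",
    "generate_expression",
    "make_paper_like_study",
]


@dataclass
class SyntheticStudyConfig:
    """Full specification of a synthetic multi-dataset study.

    ``effect_map`` maps (pathway_id, group label) to the log2 effect applied
    to member genes (multiplied by the sign of each gene's ARR); groups not
    listed get zero effect.  ``dataset_partition`` maps dataset -> {label ->
    sample count}; labels appearing in ``groups`` are analysis groups, other
    labels (e.g. matched controls) only serve as references.
    ``group_meta`` supplies per-label annotation rules: condition, an
    inclusive age range in years, and/or a passage number.
    """

    n_pathways: int
    genes_per_pathway: int
    groups: dict[str, int]
    dataset_partition: dict[str, dict[str, int]]
    reference_label: dict[str, str]
    group_meta: dict[str, dict]
    effect_map: dict[tuple[str, str], float] = field(default_factory=dict)
    background_genes: int = 100
    activator_fraction: float = 0.7
    graded_fraction: float = 0.0
    noise_sd: float = 0.25
    dataset_offset_sd: float = 0.2
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathways < 1 or self.genes_per_pathway < 1:
            raise ValueError("n_pathways and genes_per_pathway must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.activator_fraction <= 1.0:
            raise ValueError("activator_fraction must be in [0,1]")
        ids = set(self.pathway_ids())
        labels = {l for part in self.dataset_partition.values() for l in part}
        for (pid, grp) in self.effect_map:
            if pid not in ids:
                raise ValueError(f"effect_map references unknown pathway {pid!r}")
            if grp not in labels:
                raise ValueError(f"effect_map references unknown group {grp!r}")
        for g, n in self.groups.items():
            total = sum(part.get(g, 0) for part in self.dataset_partition.values())
            if total != n:
                raise ValueError(
                    f"group {g!r}: partition places {total} samples, config says {n}"
                )
        for ds, ref in self.reference_label.items():
            if ds not in self.dataset_partition:
                raise ValueError(f"reference for unknown dataset {ds!r}")
            if self.dataset_partition[ds].get(ref, 0) < 1:
                raise ValueError(f"dataset {ds!r}: reference label {ref!r} has no samples")

    def pathway_ids(self) -> list[str]:
        width = max(2, len(str(self.n_pathways)))
        return [f"PW{i + 1:0{width}d}" for i in range(self.n_pathways)]


@dataclass
class GroundTruth:
    """Planted truth for a synthetic study.

    ``pas_sign``: expected sign (+1/-1/0) of the mean PAS of each
    (pathway, group).  ``venn_region``: for presets, the intended Venn
    region per pathway (None = no equivalent subset intended).
    ``near_zero``: pathways planted null in every group.
    ``passage_trends``: intended drift label per pathway, when applicable.
    """

    pas_sign: dict[tuple[str, str], int]
    venn_region: dict[str, tuple[str, ...] | None] = field(default_factory=dict)
    near_zero: set[str] = field(default_factory=set)
    passage_trends: dict[str, str] = field(default_factory=dict)


@dataclass
class StudyBundle:
    """Everything needed to run the pipeline on one synthetic study."""

    config: SyntheticStudyConfig
    collection: PathwayCollection
    matrices: dict[str, ExpressionMatrix]
    annotations: list[SampleAnnotation]
    groups: dict[str, list[tuple[str, str]]]
    reference: dict[str, list[str]]
    truth: GroundTruth


def generate_pathway_collection(
    config: SyntheticStudyConfig, rng: np.random.Generator
) -> PathwayCollection:
    """Random pathway collection with the configured sizes and role mix.

    Gene sets are disjoint across pathways (gene symbols are synthetic
    tokens).  Each gene is an activator (+1.0) with probability
    ``activator_fraction``, else a repressor (-1.0); a ``graded_fraction``
    of roles is softened to +/-0.5.
    """
    pathways = []
    gene_counter = 0
    for pid in config.pathway_ids():
        roles = {}
        for _ in range(config.genes_per_pathway):
            gene_counter += 1
            arr = 1.0 if rng.random() < config.activator_fraction else -1.0
            if config.graded_fraction and rng.random() < config.graded_fraction:
                arr *= 0.5
            roles[f"G{gene_counter:05d}"] = arr
        pathways.append(PathwayDefinition(pathway_id=pid, display_name=pid, gene_roles=roles))
    return PathwayCollection(pathways=pathways, collection_name="synthetic")


def _sample_age(meta: dict, rng: np.random.Generator) -> float | None:
    rng_range = meta.get("age_range")
    if rng_range is None:
        return None
    lo, hi = rng_range
    return float(rng.integers(int(lo), int(hi) + 1))


def generate_expression(
    config: SyntheticStudyConfig,
    collection: PathwayCollection,
    rng: np.random.Generator,
) -> tuple[dict[str, ExpressionMatrix], list[SampleAnnotation], GroundTruth]:
    """Simulate linear-scale expression matrices plus annotations and truth.

    Per gene g and sample s of label L in dataset d:

        log2 x = baseline_g + offset_{g,d} + sign(ARR_g) * effect(pathway(g), L)
                 + Normal(0, noise_sd^2)

    exported as 2**x.  Reference labels carry no effect unless explicitly
    present in the effect map.
    """
    gene_pathway: dict[str, str] = {}
    gene_sign: dict[str, float] = {}
    for p in collection:
        for g, arr in p.gene_roles.items():
            gene_pathway[g] = p.pathway_id
            gene_sign[g] = float(np.sign(arr))
    genes = list(gene_pathway)
    genes += [f"BG{i + 1:05d}" for i in range(config.background_genes)]
    n_genes = len(genes)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_genes)

    matrices: dict[str, ExpressionMatrix] = {}
    annotations: list[SampleAnnotation] = []
    for ds_id, partition in config.dataset_partition.items():
        offset = rng.normal(0.0, config.dataset_offset_sd, n_genes)
        cols: dict[str, np.ndarray] = {}
        for label, n in partition.items():
            meta = config.group_meta.get(label, {})
            shift = np.zeros(n_genes)
            for i, g in enumerate(genes):
                pid = gene_pathway.get(g)
                if pid is not None:
                    eff = config.effect_map.get((pid, label), 0.0)
                    if eff:
                        shift[i] = gene_sign[g] * eff
            for j in range(n):
                sid = f"{ds_id}_{label}_{j + 1}"
                log2 = baseline + offset + shift + rng.normal(0, config.noise_sd, n_genes)
                cols[sid] = np.power(2.0, log2)
                annotations.append(
                    SampleAnnotation(
                        sample_id=sid,
                        dataset_id=ds_id,
                        condition=meta.get("condition", "normal"),
                        age=_sample_age(meta, rng),
                        passage=meta.get("passage"),
                    )
                )
        values = pd.DataFrame(cols, index=genes).clip(lower=EPS_EXPR)
        matrices[ds_id] = ExpressionMatrix(values=values, dataset_id=ds_id)

    pas_sign: dict[tuple[str, str], int] = {}
    labels = {l for part in config.dataset_partition.values() for l in part}
    for pid in config.pathway_ids():
        for label in labels:
            eff = config.effect_map.get((pid, label), 0.0)
            pas_sign[(pid, label)] = int(np.sign(eff))
    return matrices, annotations, GroundTruth(pas_sign=pas_sign)


def _aging4_config(seed: int) -> tuple[SyntheticStudyConfig, GroundTruth]:
    rng = np.random.default_rng(seed)
    n_pathways, genes_per = 65, 20
    width = max(2, len(str(n_pathways)))
    pids = [f"PW{i + 1:0{width}d}" for i in range(n_pathways)]
    triple = pids[:13]       # equivalent across Middle/Old/HGPS
    pair = pids[13:25]       # equivalent across Middle/HGPS only
    null = pids[25:30]       # no regulation anywhere
    others = pids[30:]       # group-specific drift magnitudes

    effect_map: dict[tuple[str, str], float] = {}
    venn_region: dict[str, tuple[str, ...] | None] = {}
    signs = {pid: (1.0 if rng.random() < 0.5 else -1.0) for pid in pids}
    for pid in triple:
        for g in ("Middle", "Old", "HGPS"):
            effect_map[(pid, g)] = signs[pid] * 1.2
        venn_region[pid] = ("HGPS", "Middle", "Old")
    for pid in pair:
        effect_map[(pid, "Middle")] = signs[pid] * 1.2
        effect_map[(pid, "HGPS")] = signs[pid] * 1.2
        effect_map[(pid, "Old")] = signs[pid] * 2.4
        venn_region[pid] = ("HGPS", "Middle")
    for pid in null:
        venn_region[pid] = ("HGPS", "Middle", "Old", "Young")
    magnitudes = np.array([0.8, 1.6, 2.4])
    for pid in others:
        perm = rng.permutation(magnitudes)
        for g, mag in zip(("Middle", "Old", "HGPS"), perm):
            effect_map[(pid, g)] = signs[pid] * float(mag)
        venn_region[pid] = None

    config = SyntheticStudyConfig(
        n_pathways=n_pathways,
        genes_per_pathway=genes_per,
        groups={"Young": 15, "Middle": 25, "Old": 16, "HGPS": 26},
        dataset_partition={
            "age1": {"Young": 4, "Middle": 7, "Old": 4},
            "age2": {"Young": 4, "Middle": 6, "Old": 4},
            "age3": {"Young": 4, "Middle": 6, "Old": 4},
            "age4": {"Young": 3, "Middle": 6, "Old": 4},
            "hgps1": {"HGPS": 9, "Control": 5},
            "hgps2": {"HGPS": 9, "Control": 5},
            "hgps3": {"HGPS": 8, "Control": 5},
        },
        reference_label={
            "age1": "Young",
            "age2": "Young",
            "age3": "Young",
            "age4": "Young",
            "hgps1": "Control",
            "hgps2": "Control",
            "hgps3": "Control",
        },
        group_meta={
            "Young": {"condition": "normal", "age_range": (15, 30)},
            "Middle": {"condition": "normal", "age_range": (40, 55)},
            "Old": {"condition": "normal", "age_range": (60, 85)},
            "HGPS": {"condition": "HGPS", "age_range": (2, 16)},
            # matched healthy children: excluded from the age bins, reference only
            "Control": {"condition": "normal", "age_range": (2, 14)},
        },
        effect_map=effect_map,
        background_genes=200,
        noise_sd=0.25,
        seed=seed,
    )
    truth = GroundTruth(pas_sign={}, venn_region=venn_region, near_zero=set(null))
    return config, truth


def _senescence_config(seed: int) -> tuple[SyntheticStudyConfig, GroundTruth]:
    rng = np.random.default_rng(seed)
    n_pathways, genes_per = 20, 15
    width = max(2, len(str(n_pathways)))
    pids = [f"PW{i + 1:0{width}d}" for i in range(n_pathways)]
    up, down, wobble, flat = pids[:5], pids[5:10], pids[10:15], pids[15:]
    case_groups = ("p50", "p70", "p80")
    effect_map: dict[tuple[str, str], float] = {}
    trends: dict[str, str] = {}
    for pid in up:
        for g, e in zip(case_groups, (0.8, 1.6, 2.4)):
            effect_map[(pid, g)] = e
        trends[pid] = "steadily_up"
    for pid in down:
        for g, e in zip(case_groups, (0.8, 1.6, 2.4)):
            effect_map[(pid, g)] = -e
        trends[pid] = "steadily_down"
    for pid in wobble:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for g, e in zip(case_groups, (0.8, 2.4, 1.2)):
            effect_map[(pid, g)] = sign * e
        trends[pid] = "non_monotonic"
    for pid in flat:
        trends[pid] = "flat"

    config = SyntheticStudyConfig(
        n_pathways=n_pathways,
        genes_per_pathway=genes_per,
        groups={"p30": 3, "p50": 4, "p70": 3, "p80": 2},
        dataset_partition={"sen1": {"p30": 3, "p50": 4, "p70": 3, "p80": 2}},
        reference_label={"sen1": "p30"},
        group_meta={
            "p30": {"condition": "normal", "passage": 30},
            "p50": {"condition": "normal", "passage": 50},
            "p70": {"condition": "normal", "passage": 70},
            "p80": {"condition": "normal", "passage": 80},
        },
        effect_map=effect_map,
        background_genes=100,
        noise_sd=0.15,
        seed=seed,
    )
    truth = GroundTruth(pas_sign={}, passage_trends=trends)
    return config, truth


def make_paper_like_study(preset: str, seed: int = 0) -> StudyBundle:
    """Generate a full study bundle for one of the built-in presets.

    ``aging4``: four age/disease groups (15/25/16/26 samples) over seven
    pseudo-datasets with planted Venn structure (13 triple-equivalent, 12
    pair-equivalent, 5 null/near-zero, 35 drifting pathways).
    ``senescence``: one replicative-senescence series (passages 30/50/70/80,
    3/4/3/2 samples) with planted passage trends.
    """
    if preset == "aging4":
        config, truth = _aging4_config(seed)
    elif preset == "senescence":
        config, truth = _senescence_config(seed)
    else:
        raise ValueError(f"unknown preset {preset!r} (expected 'aging4' or 'senescence')")
    rng = np.random.default_rng(seed)
    collection = generate_pathway_collection(config, rng)
    matrices, annotations, base_truth = generate_expression(config, collection, rng)
    truth.pas_sign = base_truth.pas_sign

    if preset == "aging4":
        groups = assemble_groups(annotations, matrices)
    else:
        groups = {g: [] for g in config.groups}
        for a in annotations:
            groups[f"p{a.passage}"].append((a.dataset_id, a.sample_id))
    reference = {
        ds: [
            a.sample_id
            for a in annotations
            if a.dataset_id == ds and a.sample_id.startswith(f"{ds}_{ref}_")
        ]
        for ds, ref in config.reference_label.items()
    }
    return StudyBundle(
        config=config,
        collection=collection,
        matrices=matrices,
        annotations=annotations,
        groups=groups,
        reference=reference,
        truth=truth,
    )
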