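#!/usr/bin/env python
"""Summarize signalome drift: sample similarity, PCA and passage trends.

Part 1 — on the simulated aging study's PAS matrix: Pearson correlation
with hierarchical clustering and a 3-component PCA, checking that HGPS
profiles sit closer to Old than to Young (the premature-aging signature).
Part 2 — on a simulated replicative-senescence series (passages 30
reference / 50 / 70 / 80): per-pathway trend labels along passage number.
Writes correlation/PCA tables under results/aging4/ and the drift table
under results/senescence/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pasdrift import (
    PASMatrix,
    compute_pas_matrix,
    correlation_cluster,
    make_paper_like_study,
    passage_drift,
    passage_group_means,
    pca_embed,
)

AGING = Path("results/aging4")
SEN = Path("results/senescence")
SEED = 42


def aging_geometry() -> None:
    values = pd.read_csv(AGING / "pas.tsv", sep="\t", index_col=0)
    sidecar = pd.read_csv(AGING / "sample_groups.tsv", sep="\t", index_col=0)
    pas = PASMatrix(values=values, sample_groups=sidecar["group"],
                    sample_datasets=sidecar["dataset"], mode="filtered")
    corr = correlation_cluster(pas)
    corr.correlations.rename_axis("sample_id").to_csv(AGING / "correlation.tsv", sep="\t")
    (AGING / "leaf_order.txt").write_text("\n".join(corr.leaf_order) + "\n")
    sg = pas.sample_groups

    def mean_between(g1, g2):
        s1 = [s for s in corr.correlations.index if sg[s] == g1]
        s2 = [s for s in corr.correlations.index if sg[s] == g2]
        return float(corr.correlations.loc[s1, s2].to_numpy().mean())

    emb = pca_embed(pas, n_components=3)
    coords = emb.coordinates.copy()
    coords["group"] = sg.reindex(coords.index)
    coords.rename_axis("sample_id").to_csv(AGING / "pca.tsv", sep="\t")

    def centroid(g):
        return emb.centroid([s for s in emb.coordinates.index if sg[s] == g])

    d_old = np.linalg.norm(centroid("Old") - centroid("HGPS"))
    d_young = np.linalg.norm(centroid("Young") - centroid("HGPS"))
    print("aging study geometry:")
    print(f"  mean r(HGPS, Old)   = {mean_between('HGPS', 'Old'):+.3f}")
    print(f"  mean r(HGPS, Young) = {mean_between('HGPS', 'Young'):+.3f}")
    print(f"  PC1-3 centroid distance HGPS-Old   = {d_old:6.1f}")
    print(f"  PC1-3 centroid distance HGPS-Young = {d_young:6.1f}")
    print(f"  explained variance (PC1-3): "
          f"{[round(float(v), 3) for v in emb.explained_variance_ratio]}")


def senescence_trends() -> None:
    SEN.mkdir(parents=True, exist_ok=True)
    bundle = make_paper_like_study("senescence", seed=SEED)
    pas = compute_pas_matrix(
        bundle.matrices, bundle.groups, bundle.collection, bundle.reference
    )
    means = passage_group_means(pas, ["p50", "p70", "p80"])
    profile = passage_drift(means, flat_threshold=0.05)
    tab = profile.means.copy()
    tab["trend"] = profile.labels
    tab["planted"] = pd.Series(bundle.truth.passage_trends)
    tab.rename_axis("pathway_id").to_csv(SEN / "drift.tsv", sep="\t")
    agree = int((tab["trend"] == tab["planted"]).sum())
    print("replicative senescence series (passages 50/70/80 vs 30 reference):")
    print(f"  trend labels: {profile.labels.value_counts().to_dict()}")
    print(f"  {agree}/{len(tab)} pathways match their planted trend")


def main() -> None:
    aging_geometry()
    senescence_trends()


if __name__ == "__main__":
    main()
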