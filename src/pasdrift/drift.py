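"""Sample-level drift summaries over pathway activation profiles.

Three views of a PAS matrix:

* Pearson correlation between samples' PAS column vectors with hierarchical
  clustering (distance 1 - r, complete linkage) — the sample-similarity
  heat-map view;
* PCA of samples in pathway space (pathways as variables, centered but not
  scaled) reduced to the first three components;
* passage-ordered drift labels: per pathway, successive differences of
  group-mean PAS along an ordered series of culture-passage groups are
  classified as steadily up, steadily down, flat or non-monotonic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .pas import PASMatrix

__all__ = [
    "CorrelationMatrix",
    "PCAEmbedding",
    "DriftProfile",
    "correlation_cluster",
    "pca_embed",
    "passage_group_means",
    "passage_drift",
]


@dataclass
class CorrelationMatrix:
    """Sample x sample Pearson correlations of PAS profiles plus leaf order."""

    correlations: pd.DataFrame
    leaf_order: list[str]
    linkage: np.ndarray
    excluded_samples: list[str]


@dataclass
class PCAEmbedding:
    """First principal-component coordinates per sample (samples x PCs)."""

    coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray

    def centroid(self, samples: Sequence[str]) -> np.ndarray:
        return self.coordinates.loc[list(samples)].to_numpy().mean(axis=0)


@dataclass
class DriftProfile:
    """Ordered group-mean PAS per pathway with a trend label."""

    means: pd.DataFrame
    labels: pd.Series
    flat_threshold: float


def _pas_frame(pas: PASMatrix | pd.DataFrame) -> pd.DataFrame:
    return pas.values if isinstance(pas, PASMatrix) else pas


def correlation_cluster(
    pas: PASMatrix | pd.DataFrame,
    linkage_method: str = "complete",
) -> CorrelationMatrix:
    """Pearson correlation of PAS columns with hierarchical clustering.

    Samples with constant PAS across pathways have no defined correlation;
    they are excluded with a warning.  Clustering uses distance 1 - r.
    """
    df = _pas_frame(pas)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need >= 2 pathways and >= 2 samples")
    finite = df.dropna(axis=0, how="any")
    sds = finite.std(axis=0, ddof=0)
    excluded = list(sds.index[sds == 0.0])
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} constant-PAS samples from correlation: "
            f"{excluded}"
        )
    kept = finite.drop(columns=excluded)
    if kept.shape[1] < 2:
        raise ValueError("fewer than 2 samples with non-constant PAS")
    corr = np.corrcoef(kept.to_numpy(), rowvar=False)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=kept.columns, columns=kept.columns)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    order = [kept.columns[i] for i in hierarchy.leaves_list(Z)]
    return CorrelationMatrix(
        correlations=corr_df, leaf_order=order, linkage=Z, excluded_samples=excluded
    )


def pca_embed(
    pas: PASMatrix | pd.DataFrame,
    n_components: int = 3,
) -> PCAEmbedding:
    """PCA of samples in pathway space (variables centered, not scaled).

    Components are SVD-based; if the data rank is below ``n_components`` the
    embedding is truncated with a warning.
    """
    df = _pas_frame(pas).dropna(axis=0, how="any")
    X = df.to_numpy().T  # samples x pathways
    n_samples, n_feat = X.shape
    if n_samples < 4:
        raise ValueError("PCA embedding needs >= 4 samples")
    max_comp = min(n_samples, n_feat)
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} exceeds data rank bound {max_comp}; truncating"
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PCAEmbedding(
        coordinates=pd.DataFrame(coords, index=df.columns, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def passage_group_means(
    pas: PASMatrix,
    ordered_groups: Sequence[str],
) -> pd.DataFrame:
    """Mean PAS per pathway for each passage group, in the given order."""
    cols = {}
    for g in ordered_groups:
        samples = pas.sample_groups.index[pas.sample_groups == g]
        if len(samples) == 0:
            raise ValueError(f"passage group {g!r} has no samples")
        cols[g] = pas.values[list(samples)].mean(axis=1)
    return pd.DataFrame(cols, columns=list(ordered_groups))


def passage_drift(
    group_means: pd.DataFrame,
    flat_threshold: float = 0.05,
) -> DriftProfile:
    """Classify each pathway's trend along ordered passage groups.

    With successive group-mean differences d_i: ``steadily_up`` if all
    d_i > threshold, ``steadily_down`` if all d_i < -threshold, ``flat`` if
    all |d_i| <= threshold, otherwise ``non_monotonic``.  Adding a constant
    to every group of a pathway leaves the label unchanged.
    """
    if group_means.shape[1] < 3:
        raise ValueError("need >= 3 ordered passage groups")
    if group_means.isna().to_numpy().any():
        raise ValueError("NaN group means; check pathway coverage per group")
    diffs = np.diff(group_means.to_numpy(), axis=1)
    labels = []
    for d in diffs:
        if np.all(d > flat_threshold):
            labels.append("steadily_up")
        elif np.all(d < -flat_threshold):
            labels.append("steadily_down")
        elif np.all(np.abs(d) <= flat_threshold):
            labels.append("flat")
        else:
            labels.append("non_monotonic")
    return DriftProfile(
        means=group_means,
        labels=pd.Series(labels, index=group_means.index, name="trend"),
        flat_threshold=flat_threshold,
    )
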