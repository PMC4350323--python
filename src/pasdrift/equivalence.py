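"""Equivalence tests for pathway-activation similarity between groups.

Unlike a difference test, an equivalence test takes *relevant difference* as
its null hypothesis: H0 says the group PAS distributions differ by at least a
standardized margin, and rejecting H0 declares the groups similar.  Following
the standardized-difference framework of Wellek, the pairwise test uses the
two-sample pooled t statistic and declares equivalence when

    |t| < sqrt( F^-1_{1, N-2; lambda}(alpha) ),   lambda = eps^2 * n1*n2 / N,

and the k-group test (equivalence one-way ANOVA) uses the F statistic with

    F < F^-1_{k-1, N-k; lambda}(alpha),           lambda = N * eps^2,

where the critical values are lower alpha-quantiles of the *noncentral* F
distribution at the boundary noncentrality.  The margins are expressed in
pooled-standard-deviation units so that verdicts are comparable across
pathways with different PAS scales; the defaults are eps = 0.74 for pairs
and 0.74/sqrt(2) for three- and four-group comparisons at alpha = 0.05.

Per-pathway verdicts over all group subsets are summarized into Venn
regions: a pathway is assigned to the largest subset of groups declared
equivalent (ties broken by the smallest test statistic), tagged with the
sign of its pooled mean PAS over that subset, and optionally flagged as
"near zero" when its grand mean is small against the pooled spread.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import special, stats

from .pas import PASMatrix

__all__ = [
    "EPSILON_PAIR",
    "EPSILON_MULTI",
    "EquivalenceResult",
    "VennSummary",
    "noncentral_f_quantile",
    "equivalence_t_test",
    "equivalence_f_test",
    "venn_similarity",
    "near_zero_pathways",
]

logger = logging.getLogger(__name__)

#: Default standardized equivalence margin for pairwise t-tests.
EPSILON_PAIR = 0.74
#: Default margin for 3- and 4-group equivalence ANOVA, 0.74/sqrt(2).
EPSILON_MULTI = 0.74 / math.sqrt(2.0)


@dataclass
class EquivalenceResult:
    """Outcome of one equivalence comparison for one pathway."""

    comparison: tuple[str, ...]
    statistic: float
    df: tuple[int, int]
    noncentrality: float
    critical_value: float
    epsilon: float
    alpha: float
    equivalent: bool
    mean_pas_per_group: dict[str, float] = field(default_factory=dict)
    pathway_id: str | None = None

    @property
    def kind(self) -> str:
        return "t" if len(self.comparison) == 2 else "F"


def noncentral_f_quantile(prob: float, df1: int, df2: int, lam: float) -> float:
    """Quantile of the noncentral F(df1, df2; lambda) distribution.

    Returns q with CDF(q) = ``prob`` to relative tolerance 1e-8; reduces to
    the central F quantile at lambda = 0.  Raises on non-convergence.
    """
    if not 0.0 < prob < 1.0:
        raise ValueError(f"prob must be in (0,1), got {prob}")
    if df1 < 1 or df2 < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    if lam < 0:
        raise ValueError(f"noncentrality must be >= 0, got {lam}")
    if lam == 0:
        return float(stats.f.ppf(prob, df1, df2))
    q = float(special.ncfdtri(df1, df2, lam, prob))
    if not np.isfinite(q) or q < 0:
        raise RuntimeError(
            f"noncentral F quantile failed for prob={prob}, df=({df1},{df2}), "
            f"lambda={lam}: got {q}"
        )
    back = float(special.ncfdtr(df1, df2, lam, q))
    if abs(back - prob) > 1e-8 * max(prob, 1e-12):
        # polish with a bracketing root search on the CDF
        from scipy.optimize import brentq

        lo, hi = 0.0, max(2.0 * q, 1.0)
        while special.ncfdtr(df1, df2, lam, hi) < prob:
            hi *= 2.0
            if hi > 1e12:
                raise RuntimeError(
                    f"noncentral F quantile bracket failed for prob={prob}, "
                    f"df=({df1},{df2}), lambda={lam}"
                )
        q = float(
            brentq(
                lambda x: special.ncfdtr(df1, df2, lam, x) - prob,
                lo,
                hi,
                xtol=1e-14,
                rtol=1e-12,
            )
        )
    return q


def equivalence_t_test(
    x: Sequence[float],
    y: Sequence[float],
    epsilon: float = EPSILON_PAIR,
    alpha: float = 0.05,
    labels: tuple[str, str] = ("A", "B"),
    pathway_id: str | None = None,
) -> EquivalenceResult:
    """Pairwise equivalence t-test with standardized margin ``epsilon``.

    Rejecting the null of a >= epsilon standardized difference (i.e.
    ``equivalent=True``) requires |t| below the critical value derived from
    the noncentral F distribution at the boundary.  With zero pooled
    variance the test degenerates: groups are equivalent iff their means
    coincide (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("equivalence t-test needs >= 2 samples per group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite PAS values")
    N = n1 + n2
    df = N - 2
    lam = epsilon**2 * n1 * n2 / N
    crit = math.sqrt(noncentral_f_quantile(alpha, 1, df, lam))
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        logger.info("degenerate equivalence t-test (zero pooled variance)")
        equivalent = diff == 0.0
        t = 0.0 if equivalent else math.inf
    else:
        t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        equivalent = abs(t) < crit
    return EquivalenceResult(
        comparison=labels,
        statistic=float(t),
        df=(1, df),
        noncentrality=lam,
        critical_value=crit,
        epsilon=epsilon,
        alpha=alpha,
        equivalent=bool(equivalent),
        mean_pas_per_group={labels[0]: float(x.mean()), labels[1]: float(y.mean())},
        pathway_id=pathway_id,
    )


def equivalence_f_test(
    groups: Sequence[Sequence[float]],
    epsilon: float = EPSILON_MULTI,
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
    pathway_id: str | None = None,
) -> EquivalenceResult:
    """k-group equivalence one-way ANOVA with standardized margin ``epsilon``.

    Declares equivalence when the ANOVA F statistic falls below the lower
    alpha-quantile of the noncentral F(k-1, N-k; N*epsilon^2) distribution.
    With zero within-group variance the test degenerates: equivalent iff all
    group means coincide (logged).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("equivalence ANOVA needs >= 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs >= 2 samples")
    if any(not np.isfinite(a).all() for a in arrays):
        raise ValueError("non-finite PAS values")
    if labels is None:
        labels = tuple(f"G{i + 1}" for i in range(k))
    ns = np.array([len(a) for a in arrays])
    N = int(ns.sum())
    means = np.array([a.mean() for a in arrays])
    grand = float(np.concatenate(arrays).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df1, df2 = k - 1, N - k
    lam = N * epsilon**2
    crit = noncentral_f_quantile(alpha, df1, df2, lam)
    if ss_within == 0.0:
        logger.info("degenerate equivalence ANOVA (zero within-group variance)")
        equivalent = ss_between == 0.0
        f = 0.0 if equivalent else math.inf
    else:
        f = (ss_between / df1) / (ss_within / df2)
        equivalent = f < crit
    return EquivalenceResult(
        comparison=tuple(labels),
        statistic=float(f),
        df=(df1, df2),
        noncentrality=lam,
        critical_value=crit,
        epsilon=epsilon,
        alpha=alpha,
        equivalent=bool(equivalent),
        mean_pas_per_group={l: float(m) for l, m in zip(labels, means)},
        pathway_id=pathway_id,
    )


@dataclass
class VennSummary:
    """Per-pathway Venn-region assignment over group subsets.

    ``assignments`` maps pathway id -> sorted tuple of group labels (the
    largest subset declared equivalent), absent for unassigned pathways.
    ``directions`` tags each assigned pathway up/down by the sign of its
    pooled mean PAS over the assigned subset.  ``results`` retains every
    individual comparison for reporting.
    """

    groups: tuple[str, ...]
    assignments: dict[str, tuple[str, ...]]
    directions: dict[str, str]
    statistics: dict[str, float]
    results: list[EquivalenceResult]
    near_zero: set[str] = field(default_factory=set)

    def region_counts(self) -> dict[tuple[str, ...], int]:
        counts: dict[tuple[str, ...], int] = {}
        for region in self.assignments.values():
            counts[region] = counts.get(region, 0) + 1
        return counts

    def region_pathways(self, region: Sequence[str]) -> list[str]:
        key = tuple(sorted(region))
        return [p for p, r in self.assignments.items() if r == key]

    def to_json_dict(self) -> dict:
        regions: dict[str, dict] = {}
        for pid, region in self.assignments.items():
            key = "+".join(region)
            entry = regions.setdefault(
                key, {"count": 0, "pathway_ids": [], "directions": {}}
            )
            entry["count"] += 1
            entry["pathway_ids"].append(pid)
            entry["directions"][pid] = self.directions[pid]
        return {
            "groups": list(self.groups),
            "regions": regions,
            "unassigned": [
                p
                for p in self.statistics
                if p not in self.assignments
            ],
            "near_zero": sorted(self.near_zero),
        }


def _subset_order(groups: Sequence[str]) -> tuple[str, ...]:
    return tuple(sorted(groups))


def venn_similarity(
    pas: PASMatrix,
    epsilon_pair: float = EPSILON_PAIR,
    epsilon_multi: float = EPSILON_MULTI,
    alpha: float = 0.05,
    group_order: Sequence[str] | None = None,
) -> VennSummary:
    """Assign every pathway to the largest group subset declared equivalent.

    For each pathway every subset of >= 2 groups (with >= 2 finite PAS values
    per group) is tested — t-test for pairs, equivalence ANOVA for 3 and 4
    groups.  Among subsets declared equivalent the largest wins; ties are
    broken by the smallest |t| / F statistic.  Pathways with no equivalent
    subset remain unassigned.
    """
    if group_order is None:
        seen: list[str] = []
        for g in pas.sample_groups:
            if g not in seen:
                seen.append(g)
        group_order = seen
    usable = [
        g
        for g in group_order
        if (pas.sample_groups == g).sum() >= 2
    ]
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 2 samples")
    assignments: dict[str, tuple[str, ...]] = {}
    directions: dict[str, str] = {}
    statistics: dict[str, float] = {}
    results: list[EquivalenceResult] = []
    for pid in pas.pathway_ids:
        values = {g: pas.group_values(pid, g) for g in usable}
        testable = [g for g in usable if len(values[g]) >= 2]
        best: tuple[int, float, tuple[str, ...]] | None = None
        for size in range(2, len(testable) + 1):
            for combo in itertools.combinations(testable, size):
                if size == 2:
                    res = equivalence_t_test(
                        values[combo[0]],
                        values[combo[1]],
                        epsilon=epsilon_pair,
                        alpha=alpha,
                        labels=combo,
                        pathway_id=pid,
                    )
                    stat = abs(res.statistic)
                else:
                    res = equivalence_f_test(
                        [values[g] for g in combo],
                        epsilon=epsilon_multi,
                        alpha=alpha,
                        labels=combo,
                        pathway_id=pid,
                    )
                    stat = res.statistic
                results.append(res)
                if res.equivalent:
                    cand = (size, stat, _subset_order(combo))
                    if (
                        best is None
                        or cand[0] > best[0]
                        or (cand[0] == best[0] and cand[1] < best[1])
                    ):
                        best = cand
        if best is not None:
            size, stat, region = best
            assignments[pid] = region
            pooled = np.concatenate([values[g] for g in region])
            directions[pid] = "up" if pooled.mean() > 0 else "down"
            statistics[pid] = stat
        else:
            statistics[pid] = math.nan
    return VennSummary(
        groups=tuple(usable),
        assignments=assignments,
        directions=directions,
        statistics=statistics,
        results=results,
    )


def near_zero_pathways(
    pas: PASMatrix,
    venn: VennSummary,
    delta: float = 0.74,
) -> list[str]:
    """Flag all-group-equivalent pathways whose activation hovers around zero.

    Among pathways assigned to the full region (equivalent across every
    group), a pathway is flagged when |grand mean PAS| <= delta * pooled
    within-group SD.  The flags are recorded on ``venn.near_zero`` and
    returned.
    """
    full_region = _subset_order(venn.groups)
    flagged: list[str] = []
    for pid, region in venn.assignments.items():
        if region != full_region:
            continue
        values = [pas.group_values(pid, g) for g in venn.groups]
        pooled = np.concatenate(values)
        k = len(values)
        ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in values))
        df = len(pooled) - k
        sd = math.sqrt(ss_within / df) if df > 0 else 0.0
        grand = float(pooled.mean())
        if (sd == 0.0 and grand == 0.0) or abs(grand) <= delta * sd:
            flagged.append(pid)
    venn.near_zero = set(flagged)
    return flagged
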