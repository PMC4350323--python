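"""Independent, loop-based reference implementations used as test oracles.

Deliberately written with explicit Python loops and no code shared with the
package: plain arithmetic, a hand-rolled Benjamini-Hochberg step-up and a
textbook pooled t-test (only the t CDF comes from scipy).
"""

import math

from scipy.stats import t as t_dist


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values, by the textbook recursion."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, pvalues[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def pooled_t_pvalue(xs, ys):
    """Two-sided pooled-variance Student's t-test p-value."""
    n1, n2 = len(xs), len(ys)
    m1 = sum(xs) / n1
    m2 = sum(ys) / n2
    ss1 = sum((x - m1) ** 2 for x in xs)
    ss2 = sum((y - m2) ** 2 for y in ys)
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        return 1.0 if m1 == m2 else 0.0
    t = (m1 - m2) / se
    return 2.0 * t_dist.sf(abs(t), df)


def brute_force_pas(
    expression,
    genes,
    samples,
    groups,
    reference_samples,
    pathways,
    mode,
    self_reference_mode="unfiltered",
    fc_threshold=1.5,
    fdr=0.05,
):
    """PAS for every grouped sample of one dataset, by direct loops.

    ``expression`` is {gene: {sample: linear value}}; ``groups`` is
    {label: [sample, ...]}; ``pathways`` is {pathway_id: {gene: arr}}.
    Returns {sample: {pathway_id: pas}} with None for pathways having no
    gene in the matrix.
    """
    ref_mean = {}
    for g in genes:
        ref_mean[g] = sum(expression[g][s] for s in reference_samples) / len(
            reference_samples
        )
    out = {}
    for label, members in groups.items():
        if label == "excluded" or not members:
            continue
        group_mode = (
            self_reference_mode
            if set(members) == set(reference_samples)
            else mode
        )
        btif = {}
        if group_mode == "unfiltered":
            for g in genes:
                btif[g] = 1
        else:
            pvals = []
            fcs = []
            for g in genes:
                case_log = [math.log2(expression[g][s]) for s in members]
                ref_log = [math.log2(expression[g][s]) for s in reference_samples]
                if len(members) < 2 or len(reference_samples) < 2:
                    pvals.append(1.0)
                else:
                    pvals.append(pooled_t_pvalue(case_log, ref_log))
                case_mean = sum(expression[g][s] for s in members) / len(members)
                fcs.append(case_mean / ref_mean[g])
            qvals = bh_adjust(pvals)
            for g, fc, q in zip(genes, fcs, qvals):
                fold = max(fc, 1.0 / fc)
                btif[g] = 1 if (fold >= fc_threshold and q < fdr) else 0
        for s in members:
            scores = {}
            for pid, roles in pathways.items():
                present = [g for g in roles if g in expression]
                if not present:
                    scores[pid] = None
                    continue
                total = 0.0
                for g in present:
                    cnr = expression[g][s] / ref_mean[g]
                    total += roles[g] * btif[g] * math.log10(cnr)
                scores[pid] = total
            out[s] = scores
    return out
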