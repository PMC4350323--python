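# Methods

## Pathway activation scoring

The unit of analysis is a pathway × sample matrix of Pathway Activation
Strength values computed per dataset:

    PAS_p(s) = Σ_{n ∈ p} ARR_n · BTIF_n · log10( x_ns / mean(x_n, reference) )

with linear-scale expression x, the reference mean arithmetic by default
(geometric available by option).  ARR is a discrete five-level
activator/repressor coefficient (−1, −0.5, 0, +0.5, +1) carried by the
pathway collection; the three-column TSV dialect exists because GMT cannot
carry per-gene payloads (a GMT importer assigning +1 to every gene is
provided for plain gene sets).

The significance gate BTIF is decided at the (dataset, case group) level:
a two-sided pooled-variance Student's t-test on log2 values against the
dataset's reference group, Benjamini–Hochberg adjustment across all genes
of the dataset, and a linear-scale group fold change.  Filtered mode
requires max(FC, 1/FC) ≥ 1.5 and q < 0.05 (both configurable); unfiltered
mode admits every gene.  Deciding the gate at group level while CNR stays
per-sample is the only construction under which a reference group scored
against itself is exactly zero under filtering — which is also why
reference-group samples default to unfiltered self-scoring (the
`self_reference_mode` switch restores the all-zero behaviour when wanted).
The fold-change gate is applied on the linear scale and symmetrically via
max(FC, 1/FC); duplicate probes collapse by per-gene maximum (mean by
option); non-positive normalized intensities are floored at 1e-6 so logs
and ratios are defined.

Group construction for donor-age studies uses closed age bins: Young
15–30, Middle 40–55, Old 60+; the progeria condition overrides age.  Ages
in the gaps (0–14, 31–39, 56–59) are excluded rather than rounded — the
only policy that cannot contaminate neighbouring groups.

## Equivalence testing

Similarity between groups is declared by standardized-margin equivalence
tests in Wellek's framework.  The pairwise statistic is the ordinary
pooled two-sample t; equivalence is declared when |t| falls below the
square root of the lower α-quantile of the noncentral F(1, N−2)
distribution with noncentrality λ = ε²·n₁n₂/N.  The k-group test uses the
one-way ANOVA F against the lower α-quantile of noncentral F(k−1, N−k)
with λ = N·ε².  Margins are standardized (pooled-SD units) so verdicts
are comparable across pathways of different PAS scale; defaults ε = 0.74
(pairs) and 0.74/√2 (3–4 groups) at α = 0.05.  With these λ conventions
the k = 2 ANOVA coincides with the t-test when ε_t = 2·ε_F (verified in
the tests on balanced designs); the √2 rescaling keeps the *margins*
comparable across test families rather than making the two tests
identical.

Noncentral-F quantiles come from `scipy.special.ncfdtri` (central
`f.ppf` at λ = 0) with a bracketing root-search fallback ensuring
CDF∘quantile round-trips to 1e-8.  Degenerate inputs are handled
explicitly: zero pooled variance declares equivalence iff the means
coincide exactly (logged).

Venn assignment: per pathway all subsets of size ≥ 2 of the groups are
tested; among subsets declared equivalent the largest wins, ties broken
by the smallest |t| or F.  Direction is the sign of the pooled mean PAS
over the assigned subset.  "Near zero" flags full-region pathways with
|grand mean| ≤ δ · pooled within-group SD, δ = 0.74 by default (reusing
the standardized margin; configurable).  No multiplicity correction is
applied across pathways or subsets — each verdict is a per-pathway
descriptive call at level α.

A consequence worth stating plainly: the declare probability for truly
equivalent groups is bounded by P(|t| < C) with C ≈ 1.0 at n ≈ 25 per
group (≈ 0.675), while the 3/4-group ANOVA at the same sizes declares at
≈ 0.97.  Pair regions in the Venn summary therefore systematically
under-fill at realistic cohort sizes; this is a property of the test
construction, not of the implementation.

## Drift summaries

Sample similarity is Pearson correlation between PAS column vectors;
clustering is hierarchical with distance 1 − r and complete linkage
(common defaults for correlation heat maps; leaf order is otherwise
unstable, and the linkage is configurable).  Constant-PAS samples have no
defined correlation and are excluded with a warning.  PCA treats pathways
as variables, centered and *not* scaled, via full SVD; the first three
components are reported with their explained-variance fractions.

Passage trends: per pathway, successive differences of group-mean PAS
along the ordered case passage groups (the reference passage group
anchors scores near zero and is not part of the series).  All differences
> τ → steadily_up; all < −τ → steadily_down; all |d| ≤ τ → flat; else
non-monotonic.  τ = 0.05 PAS units by default — small against the planted
effects (≈ 3.6 PAS units per 0.8 log2 of coordinated regulation over 15
genes) yet above numerical noise; there is no canonical value, so it is
config-exposed.

## Synthetic studies

The generator plants known truth under the same statistical structure the
pipeline assumes: per gene, log2 expression = gene baseline
(N(8, 2²)) + per-(gene, dataset) offset (N(0, 0.2²), emulating platform
pooling; it cancels in CNR) + sign(ARR)·effect(pathway, group) +
N(0, noise_sd²), exported as 2^x.  Coupling the effect to sign(ARR) makes
"up-regulated pathway" well defined (activators up, repressors down), so
the expected PAS sign and magnitude (≈ genes · 0.301 · effect) are
analytic.  Ages are drawn uniformly from each group's bin; progeria
controls are annotated as healthy children (2–14 y), falling outside
every age bin so they serve as within-dataset references without entering
the analysis groups.

`aging4` preset: Young/Middle/Old/HGPS of 15/25/16/26 samples over four
aging datasets (Young as reference) and three progeria datasets (matched
controls as reference).  65 pathways × 20 genes plus 200 background
genes; noise_sd = 0.25 log2 (human cohort heterogeneity).  Planted
structure: 13 pathways with a common ±1.2 log2 effect in Middle/Old/HGPS;
12 with ±1.2 in Middle and HGPS but ±2.4 in Old; 5 null pathways; 35
"drift" pathways whose Middle/Old/HGPS effects are a random permutation
of ±{0.8, 1.6, 2.4} with a common sign — same direction, different
strength, mirroring progressive age drift while staying far (≥ several
pooled SDs) from any equivalence margin.  Effect sizes were chosen so
every planted gene clears both BTIF gates at the smallest per-dataset
group sizes (t ≳ 5 at n = 4 vs 4, FC ≥ 1.7 against gate 1.5).

`senescence` preset: one dataset, passages 30 (reference, 3 samples) /
50 (4) / 70 (3) / 80 (2); 20 pathways × 15 genes plus 100 background
genes; noise_sd = 0.15 log2 (clonal cell-line culture, technical-grade
variance — also keeping the false-gate probability negligible at n = 2
case samples).  Five pathways each of steadily-up (0.8/1.6/2.4 log2
across 50/70/80), steadily-down, non-monotonic (0.8/2.4/1.2) and flat.

What the generator does *not* emulate: probe-level noise, platform- or
GC-dependent artifacts, correlated noise between genes beyond the shared
dataset offset, overlapping pathway membership, and symbol aliasing.
Passing tests on synthetic studies therefore demonstrate correctness of
the computations and recoverability of planted structure under the
model's assumptions — not robustness to real microarray pathology.

## Problem sizes and determinism

The bundled analyses and tests run on the preset sizes above (≈ 1,500
genes × ≈ 100 samples per aging study, 10 seeded replicates for the
recovery study; 10⁴ Monte-Carlo replicates for boundary calibration; 10⁶
draws for the noncentral-F simulation oracle), which a laptop CPU covers
in a few minutes.  All randomness flows through `numpy.random.Generator`
seeds; identical configuration and seed reproduce every table
byte-for-byte, and the pipeline writes a manifest (config echo, package
versions, seed) alongside its outputs.

## Known limitations

* The pairwise equivalence power ceiling discussed above; pair-region
  counts are conservative at n ≲ 30 per group.
* BTIF is a group-level gate: a single outlier sample can neither gain
  nor lose a gene for itself, only shift the group statistics.
* PAS sums gene contributions without inter-gene correlation weighting;
  strongly co-expressed member genes are implicitly over-weighted.
* No batch correction across datasets is applied; cross-dataset pooling
  relies on each dataset being scored against its own internal reference.
* Equivalence verdicts are reported per pathway without multiplicity
  control; treat region counts as descriptive, not inferential.
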