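# Methods

This note documents the models, conventions and numerical choices behind
`tbiscreen`, what the synthetic generators do and do not emulate, and the
known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Injury signature and concordance

A differential-expression record is (gene, fold-change, FDR). Two
fold-change dialects are accepted: `ratio` (|FC| ≥ 1 with sign as
direction; values in (0, 1) are plain down-ratios) and `log2`. The
signature keeps exactly the genes with |FC| ≥ 1.5 on the ratio scale
(equivalently |log2 FC| ≥ log2 1.5) *and* FDR < 0.05, both thresholds
configurable, weighted by signed log2 fold-change. The filter is
idempotent: re-filtering a signature's own records is the identity.

**Concordance statistic.** The upstream service that produced the published
compound concordances does not document its formula; only its range
([−1, +1]) and interpretation are stated. We therefore use the Spearman
rank correlation of weight vectors over the gene intersection as an openly
declared stand-in: it is bounded as required, invariant to monotone
re-expression of weights, and has a trivial independent oracle. A minimum
gene overlap (default 10) guards against meaningless correlations; smaller
overlaps raise an explicit error. Published concordance values are treated
as *input data* for ranking, never as recomputation targets.

**Ranking.** Candidates are bucketed by sign (positive = mimics,
negative = reversers; exactly zero joins neither), each bucket sorted by
|concordance| descending, ties broken lexicographically by compound id for
determinism. The default bucket sizes (20/20) match the published funnel.

## Plate screen

Three percent-of-control scales, each anchored by two on-plate controls:

- viability = 100 · (drug − LPS/IFNγ+) / (1400W − LPS/IFNγ+)
- nitrite  = 100 · (drug − 1400W) / (LPS/IFNγ+ − 1400W)
- TNFα    = 100 · (drug − IL10) / (LPS/IFNγ+ − IL10)

Anchor-in gives exactly 0 % or 100 % (the ratio is computed before the
factor of 100 so the identity is exact in floating point). Values outside
[0, 100] are legal: a drug can beat its positive control, and the screen's
published outcomes include −21 % nitrite and −139 % TNFα.

**Batch combination.** Independent experiments are combined with an
additive ordinary-least-squares model, absorbance ~ condition + batch
(batch term dropped for a single batch; a confounded condition × batch
design raises rather than silently dropping terms). Normalization is
applied to the batch-adjusted condition estimates, not per well; this makes
the percentages invariant to any per-batch additive offset and pins down
the noiseless-recovery property (planted effects recovered to machine
precision through generator → batch model → normalization). Contrasts
against the inflamed-untreated reference carry two-sided t-test p-values
from the same fit.

**Scoring.** A score criterion per assay is a monotone breakpoint table
mapping percent to [0, 1] ("higher is better" for viability, "lower is
better" for nitrite/TNFα); non-monotone tables are rejected. The original
study's full criteria appendix is unavailable, and the published score
table is demonstrably not a function of the single published summary
percentages alone — equal percentages map to different published scores,
and viability 57 % scores below viability 47 % — so the published criteria
must have used additional information (e.g. the full dose–response).
The shipped defaults are therefore a documented reconstruction that
reproduces the two rows driving lead selection (trichostatin A
0.75/0.75/1 and calpain inhibitor 0.60/1/1) from their published
percentages; for full fidelity, supply per-assay scores directly (as the
acceptance checks do) or override the criteria via config. Missing assays
(e.g. TNFα not run for inactive compounds) contribute nothing to the total
and are flagged.

**Lead selection.** Toxicity is an explicit input flag (the original flag
came from microscopy images that were never published), never inferred from
assay values. Policy `total` takes the highest total score;
`viability-priority` takes the highest neuronal-viability score — the
published rationale, under which the top-total compound (calpain inhibitor)
is passed over for the best neuroprotector (trichostatin A). Ties break by
total, then name.

## Seizure outcomes

The 72-h follow-up is partitioned into [0, 24), [24, 48), [48, 72] hours
(the source prints whole-hour epoch labels without defining boundaries;
half-open bins closed at 72 are exhaustive and non-overlapping, and an
onset exactly at 24 h falls in the second epoch). Epoch decomposition
conserves counts and seconds exactly.

Conventions inferred from how the published summaries behave:

- event-free animals contribute 0 to count/duration metrics (the published
  epoch medians of 0 require this) but are excluded from latency means
  (latency is undefined without a seizure; the source averages only over
  animals with seizures);
- seizures with ungradable behavior ("unknown" Racine) are excluded from
  Racine means; the denominator is graded seizures only (93 % gradable in
  the source data).

**Fisher's exact test** is implemented in-package by full hypergeometric
enumeration with fixed margins; the two-sided p sums all tables whose
probability does not exceed the observed table's (minimum-likelihood rule),
with a 1e-7 relative slack for floating-point ties, matching the common
exact-test convention. The enumeration's pmf sums to 1 over the support for
every margin (self-check in the suite), and the result cross-checks against
an independent library implementation.

**Cohen's delta** uses the (n−1)-weighted pooled SD and no small-sample
(Hedges) correction — verified to reproduce every printed effect size from
published summaries to within ±0.01 (several to the third decimal). Sign
convention: vehicle minus treatment, so positive = favorable on damage and
seizure-burden metrics. The statistic is antisymmetric under group swap and
scale-invariant.

**Battery.** Kruskal–Wallis omnibus across groups; pairwise two-sided
Mann–Whitney vs the vehicle group, Bonferroni-corrected over the number of
pairwise tests, exact when both groups are ≤ 20 and tie-free (group sizes
here are ≤ 16) and normal-approximated with tie correction otherwise;
within-group evolution across epochs by Friedman's rank test with
Bonferroni-corrected exact sign tests as post hoc. All-tied degenerate data
return the statistic-undefined, p = 1 convention rather than an error.
The source also mentions a general linear model for time × treatment
without specifying its terms; this package deliberately reports the rank
battery plus per-epoch comparisons instead of guessing a parametric model.

## Biomarkers

ELISA reduction: corrected signal = A450 − A630; standards must be strictly
monotone in corrected signal; inversion by piecewise-linear interpolation
in log10 concentration (the kit's curve form is undocumented; log-linear
interpolation is a neutral monotone choice, switchable to linear
concentration), then multiplication by the dilution factor (default 1:6).
Out-of-range samples are flagged `below-range`/`above-range`, never
extrapolated. Pearson correlation (t-based two-sided p) relates pNF-H to
lesion area; which vehicle subgroup anchors each comparison is a config
choice because the source states it only implicitly.

## Synthetic generators

The generators emulate the *structure* of the study's data with
controllable truth; their defaults are the study conditions.

- **DE tables**: exactly round(frac_de · n_genes) genes from the
  alternative (|log2 FC| centered on the effect size, FDR < 0.05); null
  genes get FDR uniform on [0.05, 1], so with default thresholds no null
  gene can pass — a null simulation propagates to an empty signature.
- **Compound libraries**: planted mimics/reversers are the reference
  signature (±) plus Gaussian noise; other compounds are independent
  standard normals, so their concordance is centered on zero.
- **Plates**: absorbance = assay baseline + span · percent/100 + batch
  offset + Gaussian noise; replicate structure follows the source screen
  (two independent experiments; three replicates for viability, four for
  the medium assays).
- **Cohorts**: seizure onsets from an inhomogeneous Poisson process with
  rate λ(t) = r₀·e^(−kt) sampled by thinning — the simplest process
  reproducing the spontaneous frequency decay seen in untreated animals.
  Defaults are calibrated to the published untreated group: r₀ = 0.45
  events/h and k = 0.033/h give ≈ 12 seizures/animal with ≈ 87 % of
  seizures in the first 48 h and median first onset near 9 h. Durations
  are log-normal (meanlog 3.76, sdlog 0.61 ⇒ mean ≈ 52 s, matching the
  published mean ± SD; the source states no distributional form — this is
  a modeling choice). Each animal is susceptible with its group's seizure
  probability; a susceptible animal with an empty Poisson draw receives
  one onset from the normalized rate density, so occurrence matches the
  planted probability exactly. 6 % of seizures carry an ungradable Racine
  label by default. One seed per call; per-animal sub-streams are spawned
  deterministically, so output is identical seed for seed.

**What they do not emulate:** raw EEG waveforms and seizure detection,
within-animal rate heterogeneity and seizure clustering, dose–response
curvature across concentrations, plate-position effects, assay-specific
noise distributions, and histology images. Passing tests therefore show
that the *analysis* recovers planted truth under the stated generative
assumptions, not that the generative model captures every feature of real
recordings.

## Test design and problem sizes

Statistical checks are sized to be decisive yet quick: planted-shift power
and null-uniformity checks use 200–500 simulations; the null type-I check
of the Fisher and Kruskal–Wallis stages uses 2,000 replicates of the study
group structure with every group at vehicle parameters (the study
conditions with treatment effects removed), asserting the rejection rate
does not exceed the nominal 5 % plus the binomial 95 % Monte-Carlo
allowance. Exact tests on tiny, heavily tied samples are discrete, so
attained size at a fixed nominal level is lumpy; at the study-structure
null both stages run conservative. Planted-effect-size recovery is a
recovery study: the mean estimate over 20 seeds at n = 200/group must fall
within 0.1 of the truth (the single-draw sampling SE of d at that n is
itself ≈ 0.1), with the cumulative-duration ground truth computed by an
independent large-sample Monte Carlo of the same process.

## Limitations

- The concordance statistic is a stand-in; absolute values are not
  comparable to the published service's scores, though sign and ordering
  behave as required.
- Default score criteria reproduce the lead-selection-relevant published
  rows only; the full published score table requires scores as direct
  input.
- Network/pathway analysis downstream of signature merging, raw EEG
  processing, and image-based endpoints are out of scope.
- The pipeline's per-drug score uses the best-scoring concentration; the
  source scored one chosen concentration per compound.
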