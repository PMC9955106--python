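# Methods

This note documents the statistical procedures the package implements, the
choices made where a procedure is underdetermined, and what the synthetic
data can and cannot show.

## Setting and conventions

One continuous marker per subject, one binary condition label (1 = condition
present, e.g. no-reflow after primary PCI; 0 = e.g. normal flow). Higher
marker values indicate the condition; this orientation is fixed. A subject
is test-positive at threshold `c` iff `x ≥ c`. Candidate thresholds are the
sorted unique observed values plus one sentinel above the maximum (the
"nobody positive" rule). Sensitivity `Se(c) = P(x ≥ c | condition)`,
specificity `Sp(c) = P(x < c | no condition)`.

Likelihood-ratio conventions at degenerate thresholds are fixed, not
exceptional: `LR+ = Se/(1−Sp)` is `+∞` when `Sp = 1` and `Se > 0`, and 0 in
the 0/0 case (threshold above all data, nobody called positive);
`LR− = (1−Se)/Sp` is `+∞` whenever `Sp = 0` (nobody called negative).

A gray zone is the half-open interval `[lower, upper)`: `x < lower` is a
negative call, `x ≥ upper` a positive call, anything in between is gray.
With continuous data the edge convention is immaterial; with ties it is not,
so it is fixed and used identically everywhere (zone searches, reports,
histograms).

## ROC and AUC

The ROC curve is the empirical step curve over the threshold grid; the AUC
is its trapezoidal area, which equals the tie-corrected Mann–Whitney
statistic (probability that a random diseased subject outscores a random
non-diseased one, ties ½). Both routes are implemented — the trapezoid from
the package's own Se/Sp arrays, the U statistic via `scipy` — and asserted
equal to 1e−12 in the tests, with a brute-force pair-counting oracle as the
third, independent route. No smoothing, no binormal fit, no interpolation
between observed thresholds.

## Likelihood-ratio ("grey zone") trichotomization

Required post-test probabilities are converted to likelihood-ratio targets
through the odds form of Bayes' theorem (see README for the formulas).
Defaults: pre-test probability = sample prevalence; required PPV 0.6;
required NPV 0.95. At prevalence 110/510 these give LR+ ≥ 5.455 and
LR− ≤ 0.191 (3 decimals).

The scan over the threshold grid uses **first attainment**: the upper limit
is the smallest threshold whose raw empirical LR+ reaches the LR+ target,
the lower limit the largest threshold whose raw LR− is at or below the LR−
target. Consequences, both tested:

- *Exact guarantee.* On the fitting data, outside-zone calls achieve the
  requested PPV and NPV whenever the corresponding limit was attainable —
  an identity of the odds relation at the attained threshold, not an
  asymptotic property.
- *Inward small-sample bias.* Raw empirical LR curves are noisy; the first
  threshold to cross a high LR+ target typically lies below the population
  crossing, and the last to sit under a low LR− target lies above it. At
  n = 510 (110 diseased) the empirical grey zone is therefore often
  substantially narrower than its population counterpart, and in roughly a
  quarter of calibrated replicates narrower than the uncertain interval.
  Confidence intervals around the limits would quantify this; they are out
  of scope here.

Unattainable targets push the affected limit to the grid extreme (minimum
for the lower limit, sentinel for the upper) and are flagged, never raised
as errors; a crossed pair (`lower > upper`, possible on non-monotone raw
curves) collapses both limits onto the upper threshold and is flagged
degenerate. An optional isotonic-regression monotonization of both LR
curves before the scan (`smooth="isotonic"`) is available for exploration;
it is off by default because it forfeits the exact guarantee above, and in
calibrated simulations it does not remove the inward bias (the noise sits
at the targets themselves, not only in non-monotonicity).

## Uncertain-interval trichotomization

The inner cutoff is the estimated crossing point of the two class
densities: Gaussian KDEs with Silverman bandwidth, fitted on the natural-log
scale for positive-valued markers (a crossing on the log scale is a crossing
on the original scale, the Jacobian being common to both densities), root
search between the two class medians, and — among several crossings — the
one closest to the medians' midpoint. A crossing whose density is below
1e−3 of the class density peaks is treated as spurious (separated groups);
the midpoint of the class medians is then used and flagged.

Given the cutoff, the search enumerates every pair `(l, u)` from the
threshold grid with `l ≤ cutoff ≤ u`. A pair is feasible when both classes
are represented inside `[l, u)` and the within-interval sensitivity and
specificity at the cutoff are at or below the ceilings (0.55/0.55 by
default — at most marginally better than chance). Among feasible pairs the
objective is lexicographic: most subjects inside, then smaller marker-scale
width, then smaller lower limit. The both-classes-inside requirement makes
"near-chance" meaningful: without it, one-class intervals would be
vacuously feasible through the empty-denominator convention (empty
denominators report 0, flagged as undefined). With no feasible pair the
zone collapses onto the grid point just above the cutoff, flagged.

The ceilings constrain the test only *at the cutoff*, so the inside-zone
AUC is not bounded by 0.55: on large calibrated cohorts it measures
0.56–0.60, and the consistency tests assert it in (0.45, 0.61) (δ = 0.06).
Raising the ceilings can only grow the feasible set, so the inside-subject
count is non-decreasing in the ceilings; the width need not be, because the
min-width tie-break may pick a newly feasible same-count narrower pair.

This search is a concrete, brute-force-verifiable formalisation of the
uncertain-interval idea; it is not a re-implementation of any particular
existing package, and its limits are checked against exhaustive enumeration
rather than against published clinical values.

## Zone performance and comparison

Outside-zone accuracy, sensitivity and specificity are computed from the
trichotomized confusion counts, each with an exact Clopper–Pearson 95%
interval on its own denominator. Metrics with empty denominators are
reported as undefined (`None`), never as 0 or 1. Two zones are compared per
metric with an unpaired pooled two-proportion z-test (zero pooled variance
⇒ p = 1); a paired bootstrap (resample subjects, rescore both fixed zones,
doubled tail proportion of the difference distribution) is available and
labelled in the result. Group descriptives use linear-interpolation
quantiles and a two-sided asymptotic Mann–Whitney U test with tie
correction, U oriented to the diseased class.

## Synthetic cohorts

Each class is an independent log-normal, identified from a published
median/quartile summary by `μ = ln(median)`, `σ = ln(q3/q1)/(2·z₀.₇₅)`. The
fit preserves the median and the quartile ratio exactly; the individual
quartiles round-trip exactly only for log-symmetric summaries
(`median = √(q1·q3)`) — the SII calibration summaries are 0.4% and 1.3% off
log-symmetry, so their fitted quartiles land within 1.5% of the published
values. Defaults reproduce the published study conditions: 400 normal-flow
and 110 no-reflow subjects, SII summaries 690.791 (413.911–1161.518) and
2066.281 (1190.72–3493.188); NLR and PLR calibrations are provided as
constants. One `numpy` generator stream per cohort, non-diseased block
first; full-precision values, no rounding or truncation.

The calibrated pair implies a population AUC of
Φ((μ₁−μ₀)/√(σ₀²+σ₁²)) ≈ 0.839, matching the published empirical AUC — the
generator's main adequacy check (mean empirical AUC over 200 replicates is
asserted within ±0.04). What the generator does **not** emulate: cross-
marker correlation (markers are drawn independently), clinical covariates,
measurement rounding, or any departure of the true marker distribution from
log-normality — the published summaries do not identify the family, only
this two-parameter fit. Passing simulation-based tests therefore validates
the *procedures* under a realistic skewed-marker model, not the published
clinical zone limits, which depend on the non-public cohort and are not
implementation targets.

## Problem sizes and determinism

Simulation-backed tests use 400/110 cohorts (200 replicates for the AUC
check, 100 for approach comparisons), 4 000/1 100 cohorts for asymptotic
consistency checks, and 20 000/5 500 for the KDE-crossing accuracy check;
brute-force oracle comparisons run on 500 random datasets of up to 50
subjects. Every stochastic component — generator, bootstrap, property-test
datasets — is driven by explicit integer seeds, and the pipeline writes a
manifest (versions, seed, config hash) sufficient to regenerate every
number in its output bundle.
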