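# Methods

This note documents the models, numerical choices and limitations of
`gutphase` — what each stage computes, which knobs matter, what the
synthetic cohort does and does not emulate, and where design decisions
were genuinely open.

## Phase classification

A sample's class-level relative abundances of *Bacilli* (B),
*Gammaproteobacteria* (G) and *Clostridia* (C) — computed from raw
counts, before any normalization — feed a two-step decision tree:

1. `r1 = log((B + G) / C)`.  If `r1 ≤ τ` the sample is **P3**.
2. Otherwise `r2 = log(B / G)`.  If `r2 ≤ τ` the sample is **P2**,
   else **P1**.

`τ = 2` is fixed.  The log base is configurable (`ln`, `log2`,
`log10`); natural log is the default, following the dysbiosis-index
lineage this construction descends from.  Because the base changes the
decision boundary, it is an explicit parameter rather than a constant.
Ties (`r = τ` exactly) take the lower branch, per the "less than or
equal" reading.

Zero-abundance cases avoid arithmetic on empty ratios: if C = 0 the
P1|P2 branch is taken; on that branch G = 0 gives P1 and B = 0 gives
P2; a sample with exactly one focal class present belongs to that
class's phase; a sample with all three absent raises
`UnresolvablePhaseError` rather than guessing.  The ratios are
identical whether the three classes are renormalized among themselves
or over the whole community, so only the ratios of raw abundances
matter and classification is scale-invariant.

"Consecutive samples" are adjacent samples in PMA order within one
subject, regardless of gap length; the gap is recorded on each pair for
sensitivity analyses, but no maximum gap is imposed.

## Weighted UniFrac

For two abundance profiles converted to proportions, the raw distance
is `Σ_e L_e |A_e − B_e|` over all branches, where `A_e` is the fraction
of sample A descending through branch e.  The normalized variant
divides by the abundance-weighted mean root-to-leaf depth
`Σ_i d(root, i)(p_i + q_i)` and lies in [0, 1].  Raw is the default
variant.  A branch length attached to the root node is ignored: a
rooted tree's root has no branch (the root term would cancel in the
numerator anyway; scikit-bio includes it in the normalized denominator,
which is the one place the two implementations can differ).  A fixed
5-leaf class-level tree with unit branch lengths ships for synthetic
runs, where no meaningful phylogeny exists.

The same-phase versus phase-change contrast uses a two-sided Wilcoxon
rank-sum test with midranks for ties and a continuity-corrected normal
approximation; exact enumeration is used only when both groups have at
most 12 pairs and no ties.  The p-value is approximate by construction
(pairs from the same subject are dependent), and is labeled as such.
Cell means of the 3×3 phase-pair matrix average per-infant first and
then across infants by default (each infant weighted equally); pooled
averaging is available.

## Early/late changepoint

Per subject and taxon, CSS+log2 abundances over PMA are smoothed with a
cubic smoothing spline whose penalty is chosen by generalized
cross-validation, evaluated on a common grid (0.5-week steps over the
observed PMA range).  Outside a subject's observed PMA span the curve
is held constant at the boundary value: polynomial extrapolation
otherwise dominates the variance curve at the grid edges.  Subjects
with fewer than 4 samples or spanning under 4 weeks are excluded (not
imputed) with a warning; curve fitting needs support.

Functional PCA is an SVD of the centered subject × grid matrix per
taxon; the component count `K_v` is the smallest number of components
explaining ≥ 99% of that taxon's functional variation, and
reconstruction from the full decomposition is exact to numerical
precision.  The pointwise variance uses the 1/(N−1) convention; the
total curve `V̄(t)` averages over taxa.  The EARLY/LATE cutoff is the
grid argmax of `V̄` rounded to a whole week; tied maxima take the
earliest week with a flag, and a constant curve returns the earliest
grid week with a degenerate-maximum warning.  The EARLY period is
`(0, cutoff)` and LATE is `[cutoff, ∞)` — closed at the cutoff.

## Growth and covariates

Weight Z-scores use Cole's LMS method with L, M, S linearly
interpolated in PMA within sex; no extrapolation outside the chart.
For |L| ≤ 1e-4 the log-form limit `z = ln(w/M)/S` is used directly —
the power form is dominated by cancellation there and the two agree far
below chart precision.  Percentiles are `Φ(z)`.  A synthetic chart
(L = 1, S = 0.11, exponential median curve, ±4% sex offset) ships for
tests and is labeled synthetic; a published preterm chart can be
supplied as a TSV.

Nutrition covariates summarize the half-open window `[t−7d, t)` before
each sample: a dose or feed exactly 7 days prior counts, the sampling
day itself does not.  Calories are the sum of daily kcal/kg.
Macronutrient ratios default to the sum over window days of the daily
(g/kg)/(kcal/kg) ratio — the source description of these derived
variables is internally garbled (one sentence mislabels the ratio as
the enteral proportion), so the weekly-sums alternative
(`ratio_mode="weekly_ratio"`) is selectable.  The enteral proportion is
the ratio of weekly enteral to total kcal/kg sums.  Missing ledger days
contribute zero and are counted in a coverage field; a zero-calorie day
with nonzero grams flags the ratio as undefined.

The meconium-to-stool transition is the earliest diaper record whose
free text lacks the word "meconium" (case-insensitive) and which is
followed by at most two records containing it.  "Followed by" counts
*all* later records by default; a windowed reading would be a config
extension.  No qualifying record means the subject is censored.

## Mixed-effects engines

The growth models (phase-based Model B, period-based Model A) are
linear mixed models with a subject random intercept.  P3 (resp. LATE)
is the reference level coded 0; P1/P2 are separate binaries and EARLY
is coded 1.  The default fixed-effect pool is the phase/period
indicators, gestational age at birth, five nutrition covariates, six
medication flags, and every stage × covariate product.

The fitter profiles the REML criterion down to the single variance
ratio λ = σ²_subject/σ²_residual and optimizes it in one dimension,
which makes thousand-replicate calibration studies cheap; it agrees
with the statsmodels REML fit to numerical precision (verified in the
test suite).  Rank-deficient columns are dropped by pivoted QR and
reported.  Fixed-effect tests are t tests with Satterthwaite degrees
of freedom: the gradient of each coefficient's variance with respect to
(σ²_subject, σ²_residual) is formed by central differences, the
variance-component covariance from the numeric REML information, and
`df = 2 (c'Vc)² / (g' A g)`, clipped to [1, n−p] — the same recipe
lmerTest applies to lme4 fits.  At the σ²_subject = 0 boundary the fit
coincides with OLS and one-sided differences are used.

AIC uses the ML likelihood with `n_parameters = p + 2`.  Stepwise
selection is greedy and bidirectional over whole terms, deterministic
(candidates scanned in sorted order), and hierarchical: an interaction
never enters without its main effects and a main effect cannot leave
while its interaction remains.  Note the statistical fact that AIC
retains a single pure-noise covariate with probability
P(χ²₁ > 2) ≈ 0.16; "noise is removed" holds at the ~84% level, not
always.

Phase prediction is a random-intercept logistic regression fitted by
maximum likelihood with 25-node Gauss-Hermite quadrature and analytic
gradients, separately in the EARLY and LATE periods, with P1 and P2 as
separate binary outcomes against the P3 baseline and gestational age
plus PMA as controls.  Covariate significance is a likelihood-ratio
test of nested fits.  Suspected complete separation (|β| > 15) is
flagged and the model refitted with a small L2 penalty (1e-3), recorded
on the result.

The per-taxon screen regresses each taxon's CSS+log2 abundance on
gestational age, PMA, the covariate, and covariate × (PMA − mean PMA),
with a subject random intercept, and adjusts the covariate and
interaction p-values across taxa by Benjamini-Hochberg at level 0.05.
PMA is centered inside the product because with raw PMA (mean large
relative to spread) the interaction column is ~99.9% collinear with the
main effect and the screen loses essentially all power; the model space
is unchanged.

## Synthetic cohort: what it emulates

The generator's defaults are the study conditions: 95 preterm subjects,
gestational ages apportioned deterministically over strata
(23-25: 25, 26-27: 22, 28-29: 11, 30-31: 11, 32-33: 18, 34-35: 8
subjects), weekly sampling from day-of-life 7 until discharge
(PMA ≈ N(38.0, 1.6), floored at 33 weeks and capped at 46), giving
roughly 800 samples per cohort.

* **Phase progression** is a discrete-time Markov chain on the weekly
  grid.  Forward hazards are logistic in PMA —
  `p = expit(intercept + slope·(PMA − midpoint))` with
  (−0.35, 0.45, 28.9) for P1→P2 and (−0.70, 0.35, 30.4) for P2→P3 —
  and reversions occur at a fixed 0.02 per step.  Setting a slope to
  zero yields a homogeneous chain with constant per-step probability,
  which the Markov-recovery checks use.  The midpoints, slopes and the
  discharge distribution were calibrated once so that the *classified*
  phase-PMA marginals of default cohorts match the reference values
  the pipeline is validated against — about 70% of P1 samples at
  PMA ≤ 29 weeks, 84% of P2 samples in 28-36 weeks, and 78% of P3
  samples at ≥ 33 weeks — and then frozen.
* **Compositions** are genus-level Dirichlet-multinomial draws over
  eight genera in five classes, with per-phase concentrations separated
  enough that the decision tree recovers the generating phase for
  ≥ 99% of samples; library sizes are negative-binomial (mean 30,000,
  dispersion 5) floored at 1, so the 12,000-read filter has real work.
* **Growth** is generated on the Z-score scale as a Model-B linear
  predictor — phase-2 coefficient −0.7766, gestational-age slope 0.059
  per week, enteral-proportion coefficient −0.5566 (reference-fit
  values used as generator truth) plus realistic fillers — with a
  subject random intercept (SD 0.45) and residual noise (SD 0.30),
  then inverted through the LMS chart to kilograms.  Ledger rows store
  absolute kcal/grams with that day's weight, so the analysis-side
  window sums reproduce the generator's covariates exactly.
* **Nutrition** ramps from ~60 toward ~120 kcal/kg/day over two weeks;
  the enteral fraction follows a logistic ramp that is slower for more
  premature infants; protein ≈ 3.2 and lipid ≈ 2.8 g/kg/day with
  carbohydrate absorbing the remaining calories.  No distributional
  form for these is prescribed anywhere; the ranges were chosen once to
  span plausible NICU practice and are config fields.
* **Medications** are subject-level Bernoulli episodes (1-3 episodes of
  3-14 days) at cohort-like prevalences (antibiotics 0.85, diuretics
  0.57, corticosteroids 0.23, motility 0.25, PPI 0.07, H2RA 0.14).
* **Diaper records** are daily; meconium mentions stop at a clearance
  day equal to the last P1 *sample* day-of-life before the initial
  phase exit plus a Normal(4.7, 2.0) delay truncated at zero and
  rounded to a whole day.  With probability 0.1, up to two stray
  post-clearance meconium mentions are injected — the detection rule
  tolerates exactly that many.

The generator does **not** emulate: read-level sequence error, chimeras
or OTU-picking artifacts; realistic genus-level phylogeny (the bundled
tree is a labeled toy); necrotizing-enterocolitis events; informative
dropout (discharge is independent of phase); seasonal or batch effects;
breast-milk composition.  Passing tests therefore demonstrate that the
pipeline's logic and statistics behave correctly under the stated
generative assumptions, not that those assumptions capture every
property of clinical cohorts.

## Problem sizes and determinism

Replicate studies in the test suite use deliberately modest sizes —
100-replicate coefficient-recovery and changepoint studies,
1,000-replicate type-I calibrations on 40-subject designs, a
500-subject cohort for the meconium-lag pipeline — chosen as the
smallest sizes at which the Monte-Carlo error is well inside each
assertion's tolerance.  Every stochastic component takes an explicit
seed or `numpy.random.Generator`; identical configurations reproduce
cohorts bit-for-bit.

## Known limitations

* The CSS quantile's adaptive selection is a heuristic in the spirit of
  the published method, with a fixed 0.5 fallback; the original
  reference implementation's tie-breaking is not reproduced exactly.
* Satterthwaite degrees of freedom rely on numeric second derivatives;
  in near-degenerate designs the information matrix can be singular,
  in which case the residual df is used and flagged.
* The logistic mixed model uses non-adaptive quadrature; with very
  large random-intercept variances (σ ≳ 3) more nodes may be needed.
* `classify_cohort` loops per sample; for tables beyond ~10⁵ samples a
  vectorized path would be preferable.
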