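# Methods

`bwasdesign` studies how *design* choices — the spread of a covariate in the
sample, the number of measurements per participant, and whether an effect is
identified between or within subjects — change standardized effect sizes,
power and replicability in brain-wide association analyses. Everything runs
on synthetic cohorts, so each property the package claims can be checked
against a known data-generating process.

## The effect size index

For a fitted association model with tested coefficients β (m of them),
robust covariance estimate, and N participants, the Wald chi-squared
statistic is T² = N β̂ᵀ Σ̂_β⁻¹ β̂ with Σ̂_β the covariance of √N β̂. The robust
effect size index (RESI) is estimated as

    Ŝ = sqrt( max{0, (T² − m) / N} ).

Subtracting m removes the mean of the null chi-squared distribution;
truncation keeps the index non-negative. N always counts *subjects*:
duplicating every record as an extra visit leaves Ŝ unchanged. Under the
assumptions of Cohen's d (two groups, equal variances), S = d/2, so the
conventional thresholds translate to RESI 0.1 / 0.25 / 0.4 for
small / medium / large. Unlike the pooled-SD d, the index remains a
consistent estimator of its own estimand when group variances differ —
a property the test suite exercises directly.

Confidence intervals are non-parametric percentile bootstraps over whole
subjects (all visits of a resampled subject move together). The bounds are
order statistics: with 1000 replicates at the 95% level, the 25th and 975th
sorted values. Replicates whose refit fails are excluded and counted, never
retried.

### Cross-sectional-equivalent RESI (CS-RESI)

Longitudinal designs usually yield larger Ŝ for the same population, which
makes effect sizes incomparable across designs. The CS-RESI of a
longitudinal cohort is the effect size the same population would have shown
under a one-visit-per-subject design. The estimator here averages the
cross-sectional Ŝ over repeated random one-visit-per-subject subsamples
(default 20); its CI resamples subjects and draws one subsample per
bootstrap replicate. On a degenerate "longitudinal" table with one visit per
subject the estimator reduces exactly to the ordinary RESI.

## Study-level models

Cross-sectional cohorts are fitted by least squares with an HC0 sandwich
covariance (an HC1-style small-sample flag exists but is off by default, as
all analyses here are large-N). Longitudinal cohorts are fitted by GEE with
identity link, exchangeable working correlation and subject-clustered
sandwich covariance (statsmodels; convergence tolerance 1e-8, at most 100
iterations). With one observation per subject the GEE path reproduces the
least-squares coefficients, which the suite asserts to 10 significant
digits. Rows with missing values in modelled columns are dropped listwise
and the count is reported on the fit.

Age enters as a natural cubic spline. The basis replicates the standard
construction (cubic B-splines projected onto the null space of the
second-derivative constraints at the boundary knots, intercept column
dropped): df=2 places one interior knot at the median, df=3 at the 33rd and
66th percentiles; boundary knots sit at the data extremes and the basis
extrapolates linearly beyond them. Wald tests of a spline term test all its
columns jointly (m = df), and are invariant to reparametrizations within
the term's column block, so only the span of the basis matters.

### Between/within decomposition

For a time-varying covariate x, the decomposition model regresses the
outcome on the adjustment terms plus X_bl (the subject's baseline value,
constant over visits) and X_change (each visit's deviation from baseline),
by GEE. Subjects without a baseline row are excluded; a table with no
follow-up variation in x raises, because the within effect is then
undefined. Using the *baseline* value (not the subject mean) as the
between-subject term makes the between coefficient equal, in expectation,
to the baseline-only cross-sectional coefficient — so the two analyses are
directly comparable, and the sampling schemes can steer the between and
within variances separately. The between variance is the sample variance of
the baseline values; the within variance is the mean square of X_change
over all modelled rows (baseline rows contribute zeros; the convention is
stated here because either choice only rescales the quantity).

### Site effects

Multi-site heterogeneity is handled by a deliberately simple
location-adjustment: site main effects are estimated jointly with the
model's covariate terms and subtracted after centring (observation-weighted),
leaving covariate-outcome associations intact. Purely additive site shifts
are removed exactly; multiplicative (scale) differences are *not*
corrected. Empirical-Bayes harmonization is outside this package's scope.

## Targeted sampling weights

The design experiments resample a large cohort so that a covariate follows
a chosen target distribution. Weights are built in two steps:

1. **Local-frequency inversion.** Each record (or visit combination) is
   inversely weighted by the number of records within ±h of its value in
   every weighting dimension (closed intervals; the record counts itself;
   h = 0.5 years by default). This targets a uniform distribution.
2. **Target-density rescaling.** The inverse-frequency weight is multiplied
   by the target density. With u mapping the winsorized support to [−1, 1]:
   bell ∝ (1−u²)+δ and U-shaped ∝ u²+δ, with δ = 0.05 so neither the edges
   nor the centre ever get zero weight. Within-subject change targets use
   u01 ∈ [0, 1]: increasing ∝ exp(λ·u01), decreasing ∝ exp(−λ·u01), λ = 2.
   Binary covariates use class weights target/prevalence and
   (1−target)/(1−prevalence).

Values beyond the winsorization bounds are clamped *for weight assignment
only* — explicit bounds for age-like covariates, 5%/95% sample quantiles as
the generic rule — and the analysis always sees the actual stored values.
The suite asserts the weighting step never mutates the table.

Longitudinal sampling units are per-subject (baseline, follow-up, …)
combinations, weighted by the between-target density at the baseline value
times the within-target density at each change, divided by the bivariate
(or trivariate) local frequency. Because the joint frequency inversion
targets a uniform joint distribution first, the between- and within-targets
act independently: swapping the within shape leaves the implied
baseline-age marginal unchanged up to frequency-estimation noise.

Bootstrap draws are with replacement, with probability proportional to
weight; each sampled unit becomes a fresh bootstrap subject so longitudinal
fits cluster correctly. A scheme experiment records, per (scheme, n), the
mean Ŝ across B replicates, the 2.5/97.5 percentile band and the share of
replicates rejecting at α — the empirical power.

## Power, replicability, sample size

The Wald statistic for an effect of size S at sample size N is approximately
non-central F with degrees of freedom (m, N − df_model) and non-centrality
λ = N·S². Power at level α is the upper tail beyond the central-F critical
value; S = 0 returns exactly α. The original formulation fixes m = 1; the
module generalizes to m tested parameters and reduces to the m = 1 formula
exactly. Replicability — two independent identically designed studies both
rejecting — is power². The sample-size solver finds the smallest integer N
with power ≥ γ by bracketing and integer bisection (power is monotone in N,
so the result is exact); replicability targets are converted via γ = √r.
Wilson score intervals summarize empirical power from bootstrap replicates.
Following the experiment convention, empirical power is only meaningful for
associations significant in the full data; the experiment runner reports
per-replicate p-values so callers can apply that filter.

## Meta-regression of study-level effect sizes

Each study contributes one (Ŝ, SE) pair and design features computed at
baseline, one record per subject: mean, SD and adjusted Fisher–Pearson
skewness of age, proportion male, design type and N. A study with fewer
than three subjects having repeat visits is treated as cross-sectional
(baseline rows only) — the same curation rule the cohort container applies.

The meta-model regresses Ŝ on a design indicator plus df=3 natural-spline
terms of the continuous features (knots at the 33rd/66th percentiles),
weighted least squares with weight 1/SE. The 1/SE weighting (rather than
the conventional inverse-variance 1/SE²) mirrors the weighting used for the
study-level estimates; `inverse_variance=True` switches to 1/SE².
Coefficient inference uses HC0 robust standard errors (HC1/HC3 by flag).
Small collections that cannot support the spline terms can fit linear
feature terms (`spline_df=None`); the pipeline falls back automatically
below 13 studies. Partial-prediction curves vary one feature over a grid
with the others fixed at mean age 45 y, age SD 7 y, skewness 0, proportion
male 0.5; grids beyond the observed range warn, since the spline
extrapolates linearly. Benjamini–Hochberg adjustment is available for
multi-outcome p-value families.

## Synthetic cohorts

The generator draws, per subject: a baseline age from a named distribution
(normal, uniform, skew-normal — the skew-normal covers |skewness| up to
~0.99, which spans the design range explored), a sex indicator
Bernoulli(p), a covariate level u_i ~ N(0, σ_b), a stable intercept
b_i ~ N(0, σ_u); and per visit: a positive age gap, a covariate deviation
w_ij ~ N(0, σ_w), and residual noise. The outcome is

    y_ij = β₀ + f(age_ij) + β_sex·sex_i + β_b·u_i + β_w·w_ij + b_i + e_ij,

with f a fixed cubic polynomial on age standardized by the age
distribution's nominal moments — a smooth non-linearity the df=2 spline fit
can track. The observed covariate is u_i + w_ij, optionally plus visit-level
measurement noise (the two-wave behavioural variant, where the outcome
responds to the latent components only). Missingness strikes non-baseline
visits uniformly at random, so baseline-anchored models always have their
anchor row. One master seed drives everything; per-study and per-replicate
streams are spawned from it (`numpy.random.SeedSequence`), so collections
and experiments are reproducible and parallelizable.

What the generator does *not* emulate: realistic lifespan trajectories,
site-by-age interactions, informative missingness, or imaging noise
structure. Passing tests therefore demonstrate the estimators' statistical
properties under the assumed mean model and exchangeable dependence — not
robustness to the full messiness of consortium MRI data.

## Numerical choices and problem sizes

Defaults, used everywhere unless a caller overrides them: α = 0.05,
B = 1000 bootstrap replicates (desk-scale analyses and tests use 30–300),
halfwidth h = 0.5, quadratic floor δ = 0.05, exponential rate λ = 2,
replicability target 0.8. GEE: tolerance 1e-8, max 100 iterations. Wald
tests guard the degenerate all-zero case (constant outcome) and return
T² = 0 there. The test suite sizes its simulations to single-CPU desk
scale: consistency checks at n = 10⁴ with tens of replicates, recovery
studies at 200 replicates of n = 1000, scheme experiments at B = 300 —
large enough for the asserted tolerances (3 Monte-Carlo SEs or the stated
absolute bounds), small enough to run in minutes.

## Known limitations

* CS-RESI uses the subsample-averaged estimator; a closed-form estimator
  would be faster and is a natural extension point. The bootstrap CI is the
  contract.
* Site adjustment is location-only; scale heterogeneity passes through.
* The non-central-F power approximation is asymptotic; at very small N with
  heavy-tailed errors the robust Wald test's finite-sample rejection rate
  can drift from the formula (the suite pins the agreement at N = 200 under
  Gaussian errors).
* No random-effects meta-analysis (τ² heterogeneity) and no
  inverse-probability re-weighting back to population effect sizes; the
  meta-model is weighted fixed-effects regression.
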