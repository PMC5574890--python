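# Methods

This note documents the statistical model, the tunable parameters and
their defaults, the synthetic generator's scope, and the numerical and
design choices made where the design was genuinely open.

## Per-site trends

The Theil–Sen estimator takes the median of all pairwise slopes
`(y_j − y_i)/(t_j − t_i)` over pairs with distinct years; the intercept is
`median(y − slope·t)`. Its ≈29% breakdown point makes single anomalous
years (instrument changes, gap-filling artifacts) nearly harmless. The
slope SE is the half-width of Sen's 95% confidence interval divided by
1.96. The one-tailed P (H1: trend > 0) comes from the Mann–Kendall S
statistic under the normal approximation with tie and continuity
corrections; an exact permutation distribution (inversion-count
recurrence) is available for n ≤ 10 untied series. No published reference
implementation pins down which one-tailed test accompanied the published
per-site tables, so recomputed P values are not expected to match printed
ones exactly; the packaged table is used verbatim for worked-example
counts.

The cross-site bootstrap resamples the per-site slope values with
replacement B times; the statistic is the fraction of positive slopes and
the reported P is the proportion of resamples with fraction ≤ 0.5 (ties
count against the majority-increasing hypothesis). An exact enumeration at
n ≤ 3 fixes the convention in the tests. Kernel densities use a Gaussian
kernel with Silverman bandwidth; the "share increasing" figure is density
mass above zero.

## The mixed-model engine

Every panel-level fit is the Gaussian LMM

    y_i = X_i β + Z_i b_i + ε_i,   b_i ~ N(0, diag(τ₀², τ₁²)),
    ε_i ~ N(0, σ² R_i(φ)),   R_i(φ)_{st} = φ^{|year_s − year_t|}

with site *i* as the grouping factor and Z_i = [1, year − ȳear]. Choices:

- **Uncorrelated random intercept and slope** (diagonal G). The intercept
  variance is dominated by between-site flux level differences and is of
  no inferential interest; leaving out the covariance keeps the profile
  surface well behaved on 20-ish groups.
- **Gapped years** use the `φ^|Δyear|` convention rather than treating
  rows as consecutive, since panels have missing years.
- **Estimation** profiles β and σ² analytically and optimizes
  `(log g₀, log g₁, atanh-scaled φ)` by Nelder–Mead from a fixed two-point
  start grid (deterministic; `multi_start=False` uses one start). The
  per-site blocks are padded to a common length with identity covariance
  blocks and zero rows, so each objective evaluation is a single batched
  Cholesky — padding provably changes no likelihood term.
- **ML vs REML**: candidate models are ranked by ML-based AICc (models
  differ in fixed effects, where REML likelihoods are not comparable); the
  retained set is refit by REML for reported estimates.
- **AICc** counts k = fixed effects + variance/correlation parameters +
  residual variance. The criterion is undefined (error) when n ≤ k + 1.
- **P values and intervals** use the large-sample normal ratio without
  degrees-of-freedom correction; this is documented because with ~23
  groups it is mildly anticonservative (see Limitations).
- A residual-variance floor of 1e−12 keeps exactly-linear (noise-free)
  inputs finite; β is exact in that limit regardless of the floor.

## Multimodel inference

The saturated pool for a flux anomaly combines four blocks
{mean S dep, S anomaly, CO₂}, {mean N dep, N anomaly, CO₂},
{MATc, MAT anomaly, CO₂}, {MAPc, SPEI, CO₂} with within-block pairwise
interactions, plus mean-S×mean-N, MATc×MAPc and CO₂×stand-age, and the
LAI anomaly as a covariate in flux models; CO₂ enters once even though it
is listed in every block. Enumeration respects marginality (an interaction
requires both parents) and refuses to materialize more models than an
explicit cap: the full pool is astronomically large, and how the original
published analysis restricted it to its quoted totals is not derivable
from the enumeration rule alone, so this package treats the candidate pool
as an explicit analysis choice rather than asserting any particular count.

Averaging is *full* (zero-substitution): each term's estimate is
`Σ w_m β_m` with β = 0 in models excluding it; the unconditional SE is the
revised Burnham–Anderson form `Σ w_m sqrt(var_m + (β_m − β̄)²)`; relative
importance is the summed weight of models containing the term. Conditional
(subset) averaging is available behind a flag.

## Counterfactual attribution

For each temporal driver the averaged model predicts the response once
with observed covariates and once with the driver column replaced by its
per-site median (applied uniformly to every driver, including CO₂). Both
prediction series get a mixed-model trend; the contribution is the trend
difference. Design choices, each open in principle:

- Prediction trends **include site BLUPs** by default so they live on the
  same footing as the observed-trend model, which also models site
  heterogeneity; a fixed-only mode exists.
- The contribution SE treats the two trend fits as **independent**
  (conservative for the difference of two highly correlated fits).
- The unknown remainder is defined as observed − Σ contributions, so the
  additivity identity holds exactly by construction; its SE assumes
  independent terms.
- Sensitivities divide the contribution by the driver's own mixed-model
  trend with quotient-rule propagation; zero driver trend is an error,
  zero contribution degenerates to `σ_c/|t|`.
- Reported decompositions default to the 1995–2011 analysis window.

## Spatial (between-site) analysis

Per-site trends are regressed on site characteristics by WLS with weights
equal to each site's observation-year count. Forward selection greedily
minimizes AICc (a P-to-enter variant exists); interactions obey
marginality; perfectly collinear candidates are skipped and logged;
categorical predictors enter as indicator contrasts against the first
sorted level. VIF_j = 1/(1 − R²_j) from the weighted regression of
predictor j on the rest, capped at 1e6.

PMVD averages sequential R² increments over all p! entry orderings with
weights proportional to `Π_i 1/(R²_full − R²_prefix_i)`; orderings that
exhaust the explainable variance early dominate in the limit, implemented
by grouping orderings by their count of vanishing factors and keeping the
dominant group. This yields the two defining properties checked in the
tests: shares sum to the full-model R², and a predictor with a zero
full-model coefficient gets exactly zero share. Enumeration is exact and
limited to p ≤ 10; an LMG (equal-weight) fallback is provided, which lacks
the exclusion property.

## CO₂ quality control

Annual tower CO₂ should grow nearly monotonically (~2 ppm yr⁻¹). A value
is flagged when it breaks monotone growth — within each descending
year-over-year pair the culprit is the local extremum (a dip below both
neighbours, or a spike above both), defaulting to the value that dropped
below its predecessor — or when the year-over-year increase exceeds a
configurable multiple (default 3×) of the 2 ppm normal increase, measured
against the previous retained value so the recovery after a removed dip is
not itself flagged. Removed and missing values are filled by a cubic
smoothing spline with GCV-chosen smoothing on the retained values; with
fewer than 4 retained points the fill falls back to linear interpolation
between retained neighbours, then to a supplied reference series (e.g. a
global background record), else stays missing. All flags are reported and
the procedure is idempotent on its own output for well-behaved series.

Anomalies throughout are annual value minus the site's mean over its own
observed years (so site anomaly series are exactly centered); site means
over a fixed climatology window are supported by supplying precomputed
`_c` columns instead.

## Synthetic generator

The generator emulates the study conditions of a 23-forest temperate/
boreal network observed 1992–2013: one shared CO₂ ramp (start 356 ppm,
+2.0 ppm yr⁻¹, ramp noise SD 0.4 ppm), site-level wet S and N deposition
declining geometrically at −4.6% and −1.1% yr⁻¹ from site means drawn in
1–3 and 4–12 kg ha⁻¹ yr⁻¹ (multiplicative noise CV 0.05; a linear-decline
option exists), stationary AR(1) MAT and SPEI (lag correlation 0.3), and
site series of 10–20 years placed uniformly in the window. Response
anomalies are a linear, interaction-free combination of driver anomalies
with configurable true sensitivities (defaults: NEP — CO₂ 4.8, S 24, N 0,
MAT 0 in g C m⁻² yr⁻¹ per driver unit), plus a site random intercept
(SD 60 g C m⁻² yr⁻¹), a site random year-slope (SD 5 for NEP), and AR(1)
residual noise (SD 25 g C m⁻² yr⁻¹, lag correlation 0.3). Flux noise
magnitudes are not published for such networks; these values were chosen
once as field-realistic — they reproduce per-site trend SEs of the same
order as the published per-site table — and are not calibration targets.
Because the generator is linear with no interactions, the ground-truth
contribution of driver j is exactly `β_j ×` (realized mean driver trend),
stored alongside the panel.

What the generator does *not* emulate: sub-annual dynamics, spatially
correlated deposition fields, disturbance/management events, non-linear or
interactive driver effects, and measurement error structured by flux
partitioning. Passing recovery tests therefore demonstrate that the
machinery is correct under its own assumptions, not that those assumptions
hold for real towers.

## Problem sizes used in validation

The recovery study runs 200 independent 23-site × 17-year panels (the
balanced-panel variant of the generator), fitting the known-driver model
per panel and pushing it through the full contribution/sensitivity chain;
oracle comparisons use 1000 random Theil–Sen instances (n ≤ 12), exact
bootstrap enumerations at n ≤ 3, five single-site GLS instances, and
brute-force enumerations up to 12 model terms.

## Known limitations

- Wald-type SEs condition on estimated variance components. With ~23
  groups, and with CO₂ anomalies nearly collinear with the common year
  direction (whose sample-mean random slope they absorb) and with the
  smooth deposition decline, interval coverage for the CO₂ sensitivity
  runs near 88–90% rather than the nominal 95% in the recovery study.
  Kenward–Roger-type small-sample corrections would be the remedy and are
  not implemented.
- The exact Mann–Kendall option requires untied data and n ≤ 10.
- PMVD is exact but factorial; beyond p = 10 only LMG is offered.
- The enumeration cap must be raised explicitly to fit very large model
  sets; fitting hundreds of thousands of mixed models is intentionally not
  the default.
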