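# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `thermoburden`, together with what the synthetic
testbed does and does not establish.

## Two-step city-level models

The package separates the temperature and DTR effects into two sequential
quasi-Poisson regressions rather than fitting them jointly, because daily
mean temperature and DTR are correlated (both seasonally and through
weather systems) and a joint fit risks non-identifiability between the
two exposure bases.

**Step 1** regresses daily deaths on a temperature cross-basis, six
day-of-week indicators (Monday reference), and a natural cubic spline of
the day index with `round(8 * years)` total degrees of freedom, knots at
equally spaced quantiles of the day index. The quasi-Poisson treatment
estimates the usual Poisson IRLS point estimates and rescales the
covariance by the Pearson dispersion `X^2/(n - p)`; point estimates are
identical to the plain Poisson fit. IRLS convergence is declared at a
relative deviance change below 1e-9 (at most 100 iterations); the
absolute-change criterion is inappropriate because deviances scale with
the death totals. Rank deficiency is detected before fitting and reported
with the offending columns.

**Step 2** fixes the step-1 fitted log-means as an offset and regresses
the same counts on a 14-day-lag DTR cross-basis with a linear
exposure-response. The model includes its own intercept by default: the
offset already carries the average DTR contribution, and without an
intercept any mean mismatch would load onto the DTR slope. (The
no-intercept variant is available via `fit_dtr_model(...,
include_intercept=False)`.)

The first `max_lag` days (28 for temperature) are excluded from both
steps so that the step-2 offset aligns exactly with step-1 fitted days.

**A real property of the two-step estimator worth knowing:** whatever
part of the lag-weighted DTR signal lies in the span of the step-1 design
(time spline, day-of-week, temperature cross-basis) is absorbed into the
offset before step 2 sees it. On the synthetic testbed roughly half of
the lag-weighted DTR variance is in that span, so the cumulative DTR
slope is attenuated by a factor of ~2-3 while remaining exactly unbiased
under a null DTR effect (attenuation is multiplicative). Confidence
intervals are honest about sampling noise but not about this structural
attenuation; DTR effect sizes from this design should be read as
"additional DTR effect beyond anything expressible by season, trend,
day-of-week and lagged temperature".

## Bases

* Exposure (temperature): quadratic B-spline, internal knots at the
  city-specific 10th/75th/90th percentiles, boundary knots at the
  observed min/max. Percentiles use linear interpolation between order
  statistics (the "type 7" convention) — fixed, because knot placement
  feeds everything downstream.
* Exposure (DTR): linear (a single identity column).
* Lag: natural cubic spline on lag 0..L with an intercept; internal knots
  at `exp(i * log(L)/(n+1))`, i.e. equally spaced on the log-lag scale
  (three knots for L = 28, two for L = 14); boundary knots at 0 and L.
  Lag 0 is not log-shifted before knot placement; this convention is
  recorded in the serialized basis metadata rather than asserted as
  canonical, since reasonable alternatives exist.
* The natural cubic basis is the truncated-power construction (linear
  beyond the boundary knots); it spans the same function space as other
  natural-spline parameterizations, so fitted curves are invariant to
  that choice.
* Out-of-boundary values at prediction time are clamped to the boundary
  with a warning (needed for Monte Carlo draws and MMT grids near the
  extremes); a strict policy is available.
* Missingness propagates through the lag embedding: a missing exposure on
  any lagged day voids the whole row, and rows are dropped at fit time.
* Cross-basis columns are var-major; the ordering is part of the
  coefficient contract and is serialized with every fit.

## Reduction and pooling

The overall cumulative curve is the linear map that sums the lag basis
over integer lags 0..L (daily data; non-integer lags are out of scope);
covariances transform as `M V M'`. Centering is a contrast at prediction
time, so a single fit serves any reference value, and relative risks
between two exposures are independent of the chosen center.

Pooling uses a multivariate random-effects meta-regression estimated by
REML (maximum likelihood available via `method="ml"`): city vectors
`y_i ~ N(B x_i, S_i + Psi)` with within-city covariances `S_i` from the
first stage. `Psi` is optimized over its Cholesky factor (guaranteeing
positive semidefiniteness) with BFGS on the profiled restricted
likelihood, tolerance 1e-8, with a Nelder-Mead restart from near-zero
heterogeneity if needed. Meta-predictors (average temperature,
temperature range, country indicators) are standardized internally for
optimizer conditioning and the fixed effects are mapped back to the
original scale. The implementation reproduces metafor's `rma.mv`
(REML, unstructured `Psi`) to ~1e-6 on a bivariate test problem.

Heterogeneity: the multivariate Cochran Q is the GLS residual quadratic
form under `Psi = 0`, `df = k(n - p)`, and `I^2 = max(0, (Q - df)/Q)`.
BLUPs are `X_i b + Psi (Psi + S_i)^{-1} (y_i - X_i b)`; their reported
covariance combines the conditional prediction variance
`Psi - W Psi` (with `W = Psi(Psi+S_i)^{-1}`) with the propagated
fixed-effect uncertainty `(I-W) U A^{-1} U' (I-W)'`. Cities whose
first-stage fit fails are dropped with a logged warning.

## Minimum-mortality temperature and attribution

The MMT is the argmin of the (BLUP) cumulative curve evaluated on the
empirical percentile grid from the 1st to the 99th percentile in
0.1-percentile steps; ties and numerically flat curves resolve toward the
median temperature. Restricting the search to 1–99 avoids declaring an
extreme tail value, where the curve is least certain, as the reference.

Attribution uses the backward perspective: the risk on day *t* from
exposures on days *t-L..t* collapses, under the cumulative curve, to the
curve evaluated at `x_t`, giving `AN_t = (1 - exp(-b_t)) deaths_t`.
(A forward-perspective variant — attributing the mean of deaths over
days *t..t+L* to day *t*'s exposure — is available via
`AttributionSpec(perspective="forward")`; the two agree up to edge
effects when death rates are smooth.)
Extreme cold/heat use the < 2.5th / > 97.5th percentile ranges. The DTR
reference is the city-minimum observed DTR (configurable to zero), so the
DTR attributable fraction reads "deaths attributable to DTR above its
observed minimum". Country and overall totals sum attributable numbers
and deaths across cities first and then take the ratio (deaths-weighted).

Empirical 95% CIs come from `n_mc` multivariate-normal draws of the curve
coefficients (default 5000; nearest-PSD repair applied to the covariance
when needed, warned above 1e-8). The MMT is held at its point estimate
inside the Monte Carlo loop (per-draw re-estimation is a config flag);
the intervals propagate the BLUP covariance only, not the meta-stage
uncertainty in `Psi` — both choices documented here because the
literature is not explicit about either.

## Synthetic testbed

`simulate_city` generates: a sinusoidal annual temperature cycle with
AR(1) daily noise; DTR with a weaker seasonal cycle, Gaussian noise and a
0.5 °C floor; day-of-week and slow log-linear trend mortality signals;
a temperature effect that is a piecewise-linear V hinged at the city's
75th temperature percentile, distributed over lags 0..28 with geometric
weights summing to one; a linear DTR effect over lags 0..14; and
negative-binomial counts with variance `phi * mu` (Poisson when
`phi = 1`). Defaults (mean temperature 16 °C spread ±2 °C across cities,
seasonal amplitude 10 °C, AR(1) 0.7 with sd 2 °C; DTR mean 8 °C, sd
2.5 °C; baseline 30 deaths/day; cold/hot cumulative slopes 0.02/0.05
log-RR per °C; DTR slope 0.01 per °C; overdispersion 1.3) give marginal
temperature SDs ~7.4 °C and DTR SDs ~2.6 °C, matching temperate
East-Asian city climatology. Lag decay 0.8 (temperature) and 0.7 (DTR)
put the mean effect lag near 4 and 2 days respectively.

The V-curve truth makes the truth-side attributable fraction available in
closed form through the same backward formula applied to expected deaths
(`true_attributable_fraction`); day-of-week and trend terms nearly cancel
in the AF ratio. The first 28 days use partial lag sums so the expected
rate is recomputable from the series alone; those days are excluded from
fitting and attribution in any case.

What the testbed does **not** emulate: spatial correlation between
cities, humidity or pollution confounding, temperature-DTR dependence
beyond shared seasonality, missing data patterns, or reporting artifacts.
Passing recovery tests therefore demonstrates the estimation machinery is
correct under the model's own assumptions, not robustness to real-data
violations of them.

Two recovery gaps are expected and measured rather than hidden. First,
the quadratic B-spline cannot reproduce the sharp hinge of the V-truth at
the MMT: the fitted curve is biased by up to ~0.03 log-RR in the
70th–90th percentile band (where the re-centered curve's variance is
smallest), which caps pointwise 95% CI coverage of the truth at ~80–89%
of grid points and pulls the estimated total AF a few percent below the
oracle. Coverage away from the hinge is 98–100%, confirming honest
standard errors. Second, the DTR attenuation described above. Both are
properties of the prescribed estimator meeting a kinked truth, and both
would shrink under a smooth truth curve.

## Problem sizes

The default validation study is 12 cities x 6 years; replicate studies
(interval-coverage checks) use 50 replicates of scaled-down designs
(4 cities x 3 years, 500 Monte Carlo draws), sized so the full test suite
completes in a few minutes on one CPU while keeping per-replicate
estimator behavior representative.
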