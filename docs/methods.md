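# Methods

## Design and model

The package implements the time-stratified case-crossover design for daily
environmental time series as a count regression. Days are grouped into
strata by (calendar year, month, day of week); each death day is thereby
self-matched to the 3–4 other same-weekday days of the same month, which
absorbs long-term trend, season and weekday patterns non-parametrically.
The strata enter the quasi-Poisson model as fixed-effect indicator terms
rather than through a conditional likelihood: for Poisson-family models the
two are equivalent for the exposure coefficient (the test suite verifies the
equality against a conditional-likelihood fit to machine precision), and
fixed effects keep the model a plain GLM. Strata whose outcome total is zero
carry no information under conditioning and are dropped before fitting.

The full linear predictor for one cause of death is

    log E[Y_t] = alpha + Strata_t + beta * x_t
               + NS(TEMP_t, 6) + NS(RH_t, 3) + NS(PRE_t, 3) + eta * ILI_t

with `x_t` the lagged exposure in ug/m3. Point estimates are Poisson maximum
likelihood (IRLS via statsmodels); the covariance is scaled by the Pearson
dispersion phi = chi^2_P / (n - p), so the reported standard errors absorb
overdispersion. A useful identity checked in the tests: scaling all counts
k-fold multiplies phi by k and leaves both beta and its quasi-Poisson SE
unchanged, because the sqrt(phi) inflation exactly offsets the k-fold
information gain.

Missing model inputs (including the lag burn-in) are handled complete-case —
rows are dropped, never imputed — with the dropped count logged. Weekly ILI
counts are spread uniformly (count/7, constant within the week); any
smoother would assume structure the weekly data cannot support. A
public-holiday indicator can be supplied as an extra covariate column; no
holiday calendar is built in.

## Lag metrics and exposure-response

Exposure enters either at a single lag k (k = 0..10) or as the moving
average of lags 0..3 (`ma03`), the cumulative short-term metric. The first
max-lag days of the series are burn-in and excluded from fitting and burden.

Exposure-response curves replace the linear exposure term with a natural
cubic regression spline of the lagged metric. "df" is an exact column
count: interior knots at equally spaced quantiles, boundary knots at the
observed range, so df = 1 reduces identically to the linear model and the
sensitivity range df = 5..9 is well defined. A penalized smoother was the
other reading of a "smoothing spline with 3 df"; the regression spline was
chosen because its integer df matches the way the sensitivity analyses vary
df, and because the curve then nests the main log-linear model exactly.
Curves are referenced to the minimum observed exposure (log-RR = 0 there)
with pointwise 95% bands from the spline-coefficient covariance.

## Subgroups, two-pollutant models, sensitivity

Season subgroups split days into a cold period (November–April) and a warm
period (May–October); the split happens after the exposure metric is lagged
on the full series, so a moving average never straddles the season boundary,
and strata (which include the month) never straddle the subsets. Gender and
age subgroups switch the outcome column instead. Two subgroup estimates are
compared with z = (b1 - b2) / sqrt(se1^2 + se2^2), two-sided normal p. No
multiple-testing adjustment is applied across causes or subgroups — burden
tables of this kind conventionally report unadjusted 95% CIs — and the docs
flag this deliberately.

Two-pollutant models add a co-pollutant linearly under the same lag metric,
but only for pairs passing a Spearman screen (|rho| < 0.7, average ranks for
ties); screened-out pairs are refused with the correlation cited. The
sensitivity sweep refits the base model with all meteorological spline dfs
set to 3..6, and with the stratum control swapped for a long-term-trend
spline with 3..9 df per year.

## Attributable burden

For a fitted beta and target level T, the attributable deaths on day t are
AN_t = Y_t * (1 - exp(-beta * (x_t - T))) for days with x_t > T, the backward
attributable fraction applied to observed counts; days at or below T
contribute zero, and AN = sum AN_t. This per-day form is the standard
construction in the attributable-burden literature; it is bounded above by
Y_t for any beta, reduces to beta * (x_t - T) * Y_t for small effects, and a
negative beta propagates to a negative AN (reported as is). The empirical
95% CI resamples only the coefficient — beta* ~ Normal(beta_hat, SE^2), 1000
draws by default, seed required — and takes the 2.5th/97.5th percentiles of
the recomputed AN; at large draw counts it converges to the delta-method
interval (verified in the tests at 1e5 draws). Burn-in days are excluded
from both AN and the total used for preventable fractions.

PM1 target ladders are derived from the PM2.5 ladder by percentile
transfer: each PM2.5 target is located as a mid-rank empirical percentile of
the observed PM2.5 distribution and mapped to the same percentile of the
PM1 distribution. Targets outside the observed range are clamped with a
warning. Derived targets are snapped to the nearest 5 ug/m3 (falling back
to integers if that breaks monotonicity), and the applied rounding is
logged; the mid-rank percentile makes the map exactly invertible when the
two distributions coincide.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
the scale of a three-year registry from a large subtropical city: mean daily
all-cause deaths 134, mean PM1/PM2.5/PM10 of 28/38/56 ug/m3 with SDs
16/21/28, temperature 22 (6) degC, humidity 79 (10) %, pressure 1005 (7) hPa.

* Pollutants are exponentiated Gaussian processes: an annual harmonic
  (winter-peaking for PM, NO2, SO2, CO; summer-peaking for O3), a shared
  AR(1) synoptic factor, and an idiosyncratic AR(1) term, with the log-scale
  variance split so each marginal mean/SD hits its target (the log-mean is
  corrected by the Bessel-I0 factor of the harmonic). The three PM series
  load heavily on the shared factor and are size-ordered per day, so
  PM1 <= PM2.5 <= PM10 holds exactly. NO2 is constructed to exceed the 0.7
  Spearman threshold against the PMs (so the collinearity screen has a true
  positive), O3 to be nearly orthogonal to them.
* Meteorology shares the harmonic phase, which produces the negative
  PM-temperature and PM-humidity and positive PM-pressure rank correlations
  characteristic of monitoring data.
* Deaths are negative-binomial with variance = overdispersion x mean
  (default 1.3; Poisson when 1) around a log-mean combining a seasonal
  baseline, a mild cold-temperature term, and the injected effect
  beta * (lag-weighted exposure); the daily means are rescaled so their
  average equals the configured baseline exactly. The quasi-Poisson fit has
  no sampling distribution of its own, so the negative binomial is the
  generative stand-in with controllable dispersion. All-cause counts are
  split multinomially into gender and age columns that sum to the total day
  by day.
* ILI is drawn weekly (seasonal Poisson, ~350/week) and stored weekly, so
  the pipeline must exercise the weekly-to-daily conversion.
* One integer seed drives named substreams (met, shared, pollutants, ili,
  mortality, subgroups) via SeedSequence spawning; output is byte-identical
  for identical configs.

What the generator does **not** emulate: multi-station spatial structure,
measurement error and missingness patterns, pollutant chemistry, holidays,
mortality displacement (harvesting), and any nonlinearity of the true
exposure-response (the injected effect is log-linear). Passing tests
therefore demonstrate that the estimation machinery recovers known effects
under the model's own assumptions, not that those assumptions hold in any
particular city's data.

## Numerical choices and defaults

* Confounder dfs default to temperature 6, humidity 3, pressure 3; lag
  metric ma03; 95% CIs use the normal 1.96 on the beta scale.
* Injected default effect 0.002 log-RR per ug/m3 of PM2.5 (about 2% per
  10 ug/m3, the magnitude typical of such studies) spread uniformly over
  lags 0..3; overdispersion 1.3, consistent with a marginal SD of ~23 on
  134 deaths/day once the seasonal baseline is accounted for.
* Collinear designs are detected with a pivoted QR and refused naming the
  aliased columns; non-convergence raises with the IRLS deviance trace.
* Monte Carlo batteries in the tests and acceptance script use 100–200
  replicate scenarios of 3 simulated years (2 years for the subgroup
  calibration, where two fits per replicate are needed); these sizes put
  binomial noise on coverage/rejection rates at roughly 1.5–2 percentage
  points, small against the tested bands.
* The pipeline derives per-(stage, cause, pollutant) seeds from the master
  seed by hashing the cell name into a SeedSequence, so adding a cause never
  perturbs another cell's Monte Carlo results.

## Known limitations

* Cause categories are pre-aggregated daily counts; individual records and
  ICD coding are out of scope, as is multi-station exposure assignment.
* The conditional-likelihood route exists only as a test oracle; very large
  stratum counts are handled by the fixed-effects GLM, which is dense — a
  ten-year, many-cause sweep would benefit from sparse or absorbed strata.
* The percentile-transfer rounding rule (nearest 5 ug/m3) is a documented
  convention; with unavailable source data the exact published PM1 ladder
  cannot be re-derived, only the mechanism.
* Negative fitted betas yield negative attributable numbers; the package
  reproduces the mechanics without interpreting them.
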