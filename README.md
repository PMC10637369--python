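# aircrossover

Time-stratified case-crossover analysis of size-fractionated particulate
matter (PM₁ / PM₂.₅ / PM₁₀) and cause-specific daily mortality, for air
pollution epidemiologists working with city-level daily time series.

Short-term pollutant–mortality associations are estimated with an
overdispersed (quasi-Poisson) count regression

```
log E[Y_t] = α + Strata_t + β·x_t + NS(TEMP_t, 6) + NS(RH_t, 3) + NS(PRE_t, 3) + η·ILI_t
```

where `Y_t` is the daily death count for one cause, `x_t` a lagged pollutant
metric (single lag `lag k` or moving average `ma03` = mean of lags 0–3) in
μg/m³, `Strata_t` the year × month × day-of-week stratum indicators of the
time-stratified case-crossover design (self-matching days control season,
trend and weekday), `NS(·, df)` natural cubic splines of mean temperature,
relative humidity and air pressure, and `ILI_t` a daily influenza-like-illness
covariate spread from weekly counts.  Standard errors are inflated by the
Pearson dispersion φ.  Effects are reported as the percent change in
mortality per 10 μg/m³, `(exp(10·β) − 1)·100`, with the 95% CI transformed
from the β scale.

On top of the fitted β the package computes the attributable burden above
air-quality target ladders: `AN = Σ_t Y_t (1 − exp(−β(x_t − T)))` over days
exceeding target `T`, with empirical 95% CIs from 1000 Monte Carlo draws of
β, plus preventable fractions `100·AN / total deaths`.  A PM₁ ladder, which
has no official guideline, is derived from the PM₂.₅ ladder by empirical
percentile transfer.  Subgroup effects (cold/warm season, gender, age bins)
are compared with the two-sample z test on the β scale, and the sensitivity
battery refits across confounder dfs, time-control modes and two-pollutant
models screened by Spearman correlation (pairs with |ρ| ≥ 0.7 refused).

Because registry and monitor data of this kind are rarely shareable, the
package ships a calibrated synthetic-data generator
(`aircrossover.simulate`) producing seasonal, autocorrelated, right-skewed
daily series with known injected effects, so the entire pipeline is testable
end to end against ground truth.

## Worked example

```python
from aircrossover import (ScenarioConfig, generate_scenario, ModelSpec,
                          fit_quasipoisson, effect_from_fit, TargetLadder,
                          WHO_PM25_TARGETS, burden_ladder, LagSpec)

series = generate_scenario(ScenarioConfig(rng_seed=1))   # 3 years, known beta=0.002
fit = fit_quasipoisson(series, ModelSpec(outcome="deaths_all_cause",
                                         exposure="pm25"))
eff = effect_from_fit(fit)
print(f"percent change per 10 ug/m3: {eff.percent:.2f}% "
      f"(95% CI {eff.ci_low:.2f}% to {eff.ci_high:.2f}%)")

ladder = TargetLadder("pm25", WHO_PM25_TARGETS)
for b in burden_ladder(fit, series, "deaths_all_cause", ladder,
                       LagSpec.moving_average(3), seed=1)[:2]:
    print(f"target {b.target:>5.1f}: AN = {b.attributable:.0f} "
          f"(eCI {b.eci_low:.0f} to {b.eci_high:.0f}), "
          f"preventable {b.preventable_pct}% of {b.total_deaths}")
```

prints

```
percent change per 10 ug/m3: 2.15% (95% CI 1.62% to 2.69%)
target  15.0: AN = 7037 (eCI 5307 to 8603), preventable 4.8% of 146239
target  25.0: AN = 4331 (eCI 3303 to 5325), preventable 3.0% of 146239
```

i.e. a 10 μg/m³ rise in 4-day mean PM₂.₅ raises all-cause mortality by
≈2.2% in this scenario (the injected truth is 2.02%), and had daily PM₂.₅
never exceeded 15 μg/m³, about 7000 of the ~146,000 deaths in the three
simulated years (4.8%) would have been deferred.

The same analysis runs from the shell:

```sh
aircrossover all --seed 1 --out results/      # full bundle + manifest.json
aircrossover simulate --seed 1 --out data/    # synthetic daily-series CSV
aircrossover burden --seed 1                  # burden ladders with eCIs
```

Configs are flat YAML (see `PipelineConfig`); every run is deterministic
given (config, seed) and writes a manifest with the config hash.

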