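"""Orchestration: run the full study as one configured, reproducible bundle.

A run loads (or simulates) a daily series, fits every cause x pollutant x
lag-metric model, profiles lags, traces exposure-response curves, compares
subgroups (season, gender, age) with z tests, computes attributable-burden
ladders with Monte Carlo eCIs, and sweeps the sensitivity grid.  Every cell
failure is recorded rather than raised, so a wide cause sweep survives
degenerate cells.  All randomness derives from one master seed through named
substreams, so adding a cause never perturbs other cells' results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import (
    TargetLadder,
    WHO_PM10_TARGETS,
    WHO_PM25_TARGETS,
    burden_ladder,
    derive_pm1_targets,
)
from .datamodel import DailySeries, read_daily_series, write_daily_series
from .design import LagSpec, apply_lag
from .estimation import (
    FitError,
    ModelSpec,
    compare_subgroups,
    collinearity_screen,
    effect_from_fit,
    er_curve,
    fit_quasipoisson,
    fit_two_pollutant,
    lag_profile,
)
from .simulate import ScenarioConfig, generate_scenario

logger = logging.getLogger(__name__)

#: Cold period: November-April; warm period: May-October.
COLD_MONTHS = (11, 12, 1, 2, 3, 4)

AGE_BINS = ("age_0_64", "age_65_74", "age_75_84", "age_85p")


def derive_seed(master: int, *names: str) -> int:
    """Stable per-(stage, cell) substream seed below 2^31."""
    keys = [int(master)] + [zlib.crc32(n.encode()) for n in names]
    return int(np.random.SeedSequence(keys).generate_state(1)[0] % 2**31)


@dataclass
class PipelineConfig:
    """Declarative description of a full run (YAML/JSON loadable)."""

    input_path: str | None = None
    scenario: ScenarioConfig | None = field(default_factory=ScenarioConfig)
    causes: tuple[str, ...] = (
        "all_cause", "nonaccidental", "circulatory", "respiratory", "neoplasms",
    )
    pollutants: tuple[str, ...] = ("pm1", "pm25", "pm10")
    lag_specs: tuple[str, ...] = ("ma03",)
    confounder_dfs: dict[str, int] = field(
        default_factory=lambda: {"temp_mean": 6, "rh": 3, "pressure": 3})
    time_control: str = "strata"
    lag_profile_cause: str = "all_cause"
    er_df: int = 3
    target_ladders: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"pm25": WHO_PM25_TARGETS, "pm10": WHO_PM10_TARGETS})
    derive_pm1_ladder: bool = True
    sensitivity_met_dfs: tuple[int, ...] = (3, 4, 5, 6)
    sensitivity_time_dfs: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9)
    sensitivity_er_dfs: tuple[int, ...] = (5, 6, 7, 8, 9)
    n_sim: int = 1000
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scenario = raw.pop("scenario", None)
        cfg = cls(**raw)
        if scenario is not None:
            cfg.scenario = ScenarioConfig(**scenario)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Tidy result tables plus the run manifest."""

    effects: pd.DataFrame
    lag_profiles: pd.DataFrame
    er_curves: pd.DataFrame
    subgroups: pd.DataFrame
    burden: pd.DataFrame
    sensitivity: pd.DataFrame
    manifest: dict


def _effect_row(fit, cause, pollutant, lag_name) -> dict:
    eff = effect_from_fit(fit)
    return {
        "cause": cause, "pollutant": pollutant, "lag": lag_name,
        "percent": eff.percent, "ci_low": eff.ci_low, "ci_high": eff.ci_high,
        "beta": eff.beta, "se": eff.se,
        "dispersion": fit.dispersion, "n_days": fit.n_days,
    }


def load_series(config: PipelineConfig) -> DailySeries:
    if config.input_path:
        return read_daily_series(config.input_path)
    if config.scenario is None:
        raise ValueError("config needs input_path or a scenario")
    scenario = replace(
        config.scenario, rng_seed=derive_seed(config.seed, "scenario")
    )
    return generate_scenario(scenario)


def _lagged_subgroup_series(
    series: DailySeries, exposure: str, lag: LagSpec
) -> tuple[DailySeries, str]:
    """Attach the pre-lagged exposure so subset fits never lag across gaps."""
    col = f"{exposure}_{lag.name}_pre"
    out = series.subset(pd.Series(True, index=series.dates))
    out.frame[col] = apply_lag(series.frame[exposure], lag)
    return out, col


def run_subgroups(
    series: DailySeries, config: PipelineConfig, lag: LagSpec
) -> pd.DataFrame:
    """Season / gender / age subgroup effects with pairwise z tests.

    Season subsets the days (cold: Nov-Apr, warm: May-Oct) using exposure
    lagged on the full series, so the metric never averages across the
    season boundary; gender and age switch the outcome column instead.
    """
    rows = []
    for pollutant in config.pollutants:
        base, col = _lagged_subgroup_series(series, pollutant, lag)
        spec0 = ModelSpec(
            outcome="deaths_all_cause", exposure=col, lag=LagSpec.single(0),
            confounder_dfs=config.confounder_dfs, time_control=config.time_control,
        )
        fits = {}
        cold = base.dates.month.isin(COLD_MONTHS)
        for label, mask in (
            ("season:cold", pd.Series(cold, index=base.dates)),
            ("season:warm", pd.Series(~cold, index=base.dates)),
        ):
            fits[label] = fit_quasipoisson(base.subset(mask), spec0)
        for gender in ("male", "female"):
            fits[f"gender:{gender}"] = fit_quasipoisson(
                base, replace(spec0, outcome=f"deaths_all_cause_{gender}")
            )
        for age in AGE_BINS:
            fits[f"age:{age}"] = fit_quasipoisson(
                base, replace(spec0, outcome=f"deaths_all_cause_{age}")
            )
        for label, fit in fits.items():
            eff = effect_from_fit(fit)
            rows.append({
                "pollutant": pollutant, "subgroup": label,
                "percent": eff.percent, "ci_low": eff.ci_low,
                "ci_high": eff.ci_high, "beta": eff.beta, "se": eff.se,
            })
        labels = list(fits)
        for fam in ("season", "gender", "age"):
            members = [l for l in labels if l.startswith(fam)]
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    cmp = compare_subgroups(fits[a], fits[b])
                    rows.append({
                        "pollutant": pollutant, "subgroup": f"{a} vs {b}",
                        "z": cmp.z, "p_value": cmp.p_value,
                    })
    return pd.DataFrame(rows)


def sensitivity_sweep(
    series: DailySeries, base_spec: ModelSpec, config: PipelineConfig
) -> pd.DataFrame:
    """Refit the base model across the sensitivity grid.

    Settings: meteorological spline dfs 3-6 (applied to all weather terms),
    time control swapped to a trend spline with 3-9 df/year, and two-pollutant
    models for every co-pollutant passing the Spearman screen.  Each row
    reports beta, its CI and the relative deviation from the base fit.
    """
    base = fit_quasipoisson(series, base_spec)
    rows = [dict(setting="base", beta=base.beta, se=base.se, rel_dev=0.0)]

    def add(setting: str, maker) -> None:
        try:
            fit = maker()
            rel = abs(fit.beta - base.beta) / abs(base.beta) if base.beta else np.nan
            rows.append(dict(setting=setting, beta=fit.beta, se=fit.se, rel_dev=rel))
        except (FitError, ValueError) as exc:
            rows.append(dict(setting=setting, error=str(exc)))

    for df in config.sensitivity_met_dfs:
        dfs = {k: df for k in base_spec.confounder_dfs}
        add(f"met_df={df}",
            lambda d=dfs: fit_quasipoisson(series, replace(base_spec, confounder_dfs=d)))
    for df in config.sensitivity_time_dfs:
        add(f"time_df={df}/yr",
            lambda d=df: fit_quasipoisson(
                series,
                replace(base_spec, time_control="spline", time_spline_df_per_year=d)))
    screen = collinearity_screen(series)
    for co in series.exposure_columns:
        if co == base_spec.exposure:
            continue
        if screen.is_admissible(base_spec.exposure, co):
            add(f"copollutant={co}",
                lambda c=co: fit_two_pollutant(series, base_spec, c, screen))
        else:
            rows.append(dict(setting=f"copollutant={co}", error="fails Spearman screen"))
    for row in rows:
        if "beta" in row:
            eff = effect_from_fit_values(row["beta"], row["se"])
            row.update(percent=eff[0], ci_low=eff[1], ci_high=eff[2])
    return pd.DataFrame(rows)


def effect_from_fit_values(beta: float, se: float) -> tuple[float, float, float]:
    from .estimation import percent_change

    eff = percent_change(beta, se)
    return eff.percent, eff.ci_low, eff.ci_high


def run_burden(
    series: DailySeries, config: PipelineConfig, lag: LagSpec
) -> pd.DataFrame:
    """Burden ladders for each PM, deriving the PM1 ladder by percentile transfer."""
    ladders: dict[str, TargetLadder] = {
        p: TargetLadder(p, tuple(lv)) for p, lv in config.target_ladders.items()
    }
    if config.derive_pm1_ladder and "pm25" in ladders and "pm1" not in ladders:
        ladders["pm1"] = derive_pm1_targets(
            ladders["pm25"],
            series.frame["pm25"].to_numpy(),
            series.frame["pm1"].to_numpy(),
        )
    rows = []
    for cause in config.causes:
        column = f"deaths_{cause}"
        for pollutant, ladder in ladders.items():
            try:
                spec = ModelSpec(
                    outcome=column, exposure=pollutant, lag=lag,
                    confounder_dfs=config.confounder_dfs,
                    time_control=config.time_control,
                )
                fit = fit_quasipoisson(series, spec)
                results = burden_ladder(
                    fit, series, column, ladder, lag,
                    n_sim=config.n_sim,
                    seed=derive_seed(config.seed, "burden", cause, pollutant),
                )
                for r in results:
                    rows.append({
                        "cause": cause, "pollutant": pollutant, "target": r.target,
                        "attributable": r.attributable, "eci_low": r.eci_low,
                        "eci_high": r.eci_high, "total_deaths": r.total_deaths,
                        "preventable_pct": r.preventable_pct,
                    })
            except (FitError, ValueError) as exc:
                rows.append({"cause": cause, "pollutant": pollutant, "error": str(exc)})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis bundle; deterministic given the config."""
    t_start = time.time()
    timings: dict[str, float] = {}
    failures: list[dict] = []
    series = load_series(config)
    timings["load"] = time.time() - t_start

    main_lag = LagSpec.parse(config.lag_specs[0])

    t0 = time.time()
    effect_rows = []
    for cause in config.causes:
        for pollutant in config.pollutants:
            for lag_str in config.lag_specs:
                try:
                    lag = LagSpec.parse(lag_str)
                    spec = ModelSpec(
                        outcome=f"deaths_{cause}", exposure=pollutant, lag=lag,
                        confounder_dfs=config.confounder_dfs,
                        time_control=config.time_control,
                    )
                    fit = fit_quasipoisson(series, spec)
                    effect_rows.append(_effect_row(fit, cause, pollutant, lag.name))
                except (FitError, ValueError) as exc:
                    failures.append(
                        dict(stage="effects", cause=cause, pollutant=pollutant,
                             lag=lag_str, error=str(exc)))
    effects = pd.DataFrame(effect_rows)
    timings["effects"] = time.time() - t0

    t0 = time.time()
    profile_rows = []
    for pollutant in config.pollutants:
        spec = ModelSpec(
            outcome=f"deaths_{config.lag_profile_cause}", exposure=pollutant,
            lag=main_lag, confounder_dfs=config.confounder_dfs,
            time_control=config.time_control,
        )
        prof = lag_profile(series, spec)
        for name, eff in prof.estimates.items():
            profile_rows.append({
                "cause": config.lag_profile_cause, "pollutant": pollutant,
                "lag": name, "percent": eff.percent,
                "ci_low": eff.ci_low, "ci_high": eff.ci_high,
            })
        for name, err in prof.errors.items():
            failures.append(dict(stage="lag_profile", pollutant=pollutant,
                                 lag=name, error=err))
    lag_profiles = pd.DataFrame(profile_rows)
    timings["lag_profiles"] = time.time() - t0

    t0 = time.time()
    curve_rows = []
    for pollutant in config.pollutants:
        spec = ModelSpec(
            outcome=f"deaths_{config.lag_profile_cause}", exposure=pollutant,
            lag=main_lag, confounder_dfs=config.confounder_dfs,
            time_control=config.time_control,
        )
        try:
            curve = er_curve(series, spec, df=config.er_df)
            curve_rows.append(pd.DataFrame({
                "pollutant": pollutant, "exposure": curve.grid,
                "log_rr": curve.log_rr, "ci_low": curve.ci_low,
                "ci_high": curve.ci_high, "df": curve.df,
            }))
        except (FitError, ValueError) as exc:
            failures.append(dict(stage="er_curve", pollutant=pollutant, error=str(exc)))
    er_curves = (
        pd.concat(curve_rows, ignore_index=True) if curve_rows else pd.DataFrame()
    )
    timings["er_curves"] = time.time() - t0

    t0 = time.time()
    try:
        subgroups = run_subgroups(series, config, main_lag)
    except (FitError, ValueError) as exc:
        subgroups = pd.DataFrame()
        failures.append(dict(stage="subgroups", error=str(exc)))
    timings["subgroups"] = time.time() - t0

    t0 = time.time()
    burden = run_burden(series, config, main_lag)
    timings["burden"] = time.time() - t0

    t0 = time.time()
    base_spec = ModelSpec(
        outcome=f"deaths_{config.lag_profile_cause}",
        exposure=config.pollutants[min(1, len(config.pollutants) - 1)],
        lag=main_lag, confounder_dfs=config.confounder_dfs,
        time_control=config.time_control,
    )
    sensitivity = sensitivity_sweep(series, base_spec, config)
    timings["sensitivity"] = time.time() - t0

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_days": series.n_days,
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "failures": failures,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    result = PipelineResult(
        effects=effects, lag_profiles=lag_profiles, er_curves=er_curves,
        subgroups=subgroups, burden=burden, sensitivity=sensitivity,
        manifest=manifest,
    )
    if config.output_dir:
        write_bundle(result, series, config)
    return result


def write_bundle(
    result: PipelineResult, series: DailySeries, config: PipelineConfig
) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("effects", "lag_profiles", "er_curves", "subgroups",
                 "burden", "sensitivity"):
        getattr(result, name).to_csv(out / f"{name}.csv", index=False)
    write_daily_series(series, out / "daily_series.csv")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
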