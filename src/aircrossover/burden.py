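"""Attributable mortality burden above air-quality target levels.

For a fitted per-ug/m3 log relative risk beta, the deaths attributable to
exposure above a target level T on day t are

    AN_t = Y_t * (1 - exp(-beta * (x_t - T)))   for days with x_t > T,

the backward attributable fraction applied to the observed counts; summing
over days gives the period burden AN.  Empirical 95% CIs come from Monte
Carlo resampling of beta from its estimated sampling distribution (1000
draws by default).  Target ladders mirror the WHO air-quality guideline plus
interim targets (PM2.5: 15/25/37.5/50/75; PM10: 45/50/75/100/150 ug/m3);
PM1, which has no official ladder, inherits the PM2.5 ladder's empirical
percentiles mapped onto the PM1 distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import DailySeries
from .design import LagSpec, apply_lag
from .estimation import FitResult

logger = logging.getLogger(__name__)

#: WHO air-quality guideline level plus four interim targets (ug/m3).
WHO_PM25_TARGETS = (15.0, 25.0, 37.5, 50.0, 75.0)
WHO_PM10_TARGETS = (45.0, 50.0, 75.0, 100.0, 150.0)


@dataclass(frozen=True)
class TargetLadder:
    """Ascending concentration targets for one pollutant."""

    pollutant: str
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        lv = self.levels
        if not lv or any(l <= 0 for l in lv):
            raise ValueError("target levels must be positive")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("target levels must be strictly increasing")


@dataclass
class BurdenResult:
    """Attributable deaths above one target, with Monte Carlo empirical CI."""

    target: float
    attributable: float
    eci_low: float
    eci_high: float
    total_deaths: int
    preventable_pct: float


def derive_pm1_targets(
    pm25_ladder: TargetLadder,
    pm25_values: np.ndarray,
    pm1_values: np.ndarray,
    rounding: float | None = 5.0,
) -> TargetLadder:
    """Transfer a PM2.5 target ladder to PM1 by matching empirical percentiles.

    Each PM2.5 target is located as a percentile of the observed PM2.5
    distribution and the same percentile of the PM1 distribution becomes the
    PM1 target.  Targets outside the observed PM2.5 range are clamped to it
    (with a warning).  ``rounding`` snaps targets to the nearest multiple
    (default 5 ug/m3, falling back to integers if that breaks monotonicity);
    the applied rounding is logged.
    """
    pm25 = np.sort(np.asarray(pm25_values, float))
    pm1 = np.asarray(pm1_values, float)
    if len(pm25) == 0 or len(pm1) == 0:
        raise ValueError("both concentration series must be nonempty")
    levels = []
    for t in pm25_ladder.levels:
        if t < pm25[0] or t > pm25[-1]:
            logger.warning(
                "target %.1f outside observed PM2.5 range [%.1f, %.1f]; clamped",
                t, pm25[0], pm25[-1],
            )
        k = int(np.searchsorted(pm25, t, side="right"))
        # mid-rank percentile keeps the empirical-quantile map exactly
        # invertible (floating error in k/n would otherwise skip a rank)
        pct = (k - 0.5) / len(pm25) if k >= 1 else 0.0
        pct = min(max(pct, 0.0), 1.0)
        levels.append(float(np.quantile(pm1, pct, method="inverted_cdf")))

    def snap(values: list[float], unit: float) -> tuple[float, ...]:
        return tuple(max(unit, round(v / unit) * unit) for v in values)

    if rounding:
        snapped = snap(levels, rounding)
        if any(b <= a for a, b in zip(snapped, snapped[1:])):
            snapped = snap(levels, 1.0)
            logger.info("rounding to %g broke monotonicity; using integers", rounding)
        else:
            logger.info("PM1 targets rounded to nearest %g ug/m3", rounding)
        levels = list(snapped)
    return TargetLadder(pollutant="pm1", levels=tuple(levels))


def _metric_and_counts(
    series: DailySeries, cause_column: str, exposure: str, lag_metric: LagSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Lagged exposure metric and counts on non-burn-in days."""
    x = apply_lag(series.frame[exposure], lag_metric)
    ok = x.notna().to_numpy()
    return x.to_numpy()[ok], series.frame[cause_column].to_numpy()[ok]


def _an_from_arrays(
    beta: float | np.ndarray, x: np.ndarray, y: np.ndarray, target: float
) -> float | np.ndarray:
    """AN = sum_t Y_t (1 - exp(-beta (x_t - target))) over days above target.

    Vectorised over beta draws when ``beta`` is an array (days on axis 0).
    """
    over = x > target
    excess = x[over] - target
    yy = y[over]
    beta_arr = np.atleast_1d(np.asarray(beta, float))
    an = (yy[:, None] * (1.0 - np.exp(-np.outer(excess, beta_arr)))).sum(axis=0)
    return float(an[0]) if np.isscalar(beta) or np.ndim(beta) == 0 else an


def attributable_deaths(
    beta: float,
    series: DailySeries,
    cause_column: str,
    target: float,
    lag_metric: LagSpec,
    exposure: str,
) -> float:
    """Point estimate of deaths attributable to exposure above ``target``.

    Days at or below the target contribute zero; burn-in days excluded by
    the lag metric are excluded here too.  A negative beta yields a negative
    AN (deaths deferred rather than advanced), which is reported as is.
    """
    x, y = _metric_and_counts(series, cause_column, exposure, lag_metric)
    return float(_an_from_arrays(beta, x, y, target))


def mc_eci(
    fit: FitResult,
    series: DailySeries,
    cause_column: str,
    target: float,
    lag_metric: LagSpec,
    exposure: str,
    n_sim: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte Carlo empirical 95% CI for the attributable deaths.

    Draws beta* ~ Normal(beta_hat, SE^2) ``n_sim`` times, recomputes AN for
    each draw, and returns the 2.5th and 97.5th empirical percentiles.
    Deterministic given the seed.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    rng = np.random.default_rng(seed)
    draws = rng.normal(fit.beta, fit.se, size=n_sim)
    x, y = _metric_and_counts(series, cause_column, exposure, lag_metric)
    ans = _an_from_arrays(draws, x, y, target)
    low, high = np.percentile(ans, [2.5, 97.5])
    return float(low), float(high)


def preventable_fraction(an: float, total: float) -> float:
    """Share (%) of total deaths avoided if the target were never exceeded.

    Reported to one decimal place, the convention for such burden tables.
    """
    if total <= 0:
        raise ValueError("total deaths must be > 0")
    return round(100.0 * an / total, 1)


def burden_ladder(
    fit: FitResult,
    series: DailySeries,
    cause_column: str,
    ladder: TargetLadder,
    lag_metric: LagSpec,
    n_sim: int = 1000,
    seed: int = 0,
) -> list[BurdenResult]:
    """Attributable deaths with eCIs for every level of a target ladder.

    Totals for the preventable fraction count the same non-burn-in days the
    AN sum uses.
    """
    _, y = _metric_and_counts(series, cause_column, ladder.pollutant, lag_metric)
    total = int(y.sum())
    results = []
    for j, target in enumerate(ladder.levels):
        an = attributable_deaths(
            fit.beta, series, cause_column, target, lag_metric, ladder.pollutant
        )
        low, high = mc_eci(
            fit, series, cause_column, target, lag_metric, ladder.pollutant,
            n_sim=n_sim, seed=seed + j,
        )
        results.append(
            BurdenResult(
                target=target,
                attributable=an,
                eci_low=low,
                eci_high=high,
                total_deaths=total,
                preventable_pct=preventable_fraction(an, total),
            )
        )
    return results
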