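"""Quasi-Poisson effect estimation for the time-stratified case-crossover.

The model regresses daily cause-specific death counts on a lagged pollutant
metric with a log link, controlling season/trend/weekday through time-stratum
indicator terms (year x month x weekday) and weather through natural cubic
splines of mean temperature (6 df), relative humidity (3 df) and air pressure
(3 df), plus daily ILI.  Standard errors are inflated by the Pearson
dispersion, the quasi-Poisson convention for overdispersed counts.

Effects are reported as the percent change in mortality per 10 ug/m3:
(exp(10*beta) - 1) * 100, with the 95% CI computed on the beta scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy import stats

from .datamodel import DailySeries
from .design import LagSpec, SplineBasis, apply_lag, make_strata, ns_basis

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # standard-normal 97.5% quantile


class FitError(RuntimeError):
    """Raised when a model cannot be fitted (non-convergence, collinearity)."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression.

    ``outcome`` is a deaths column; ``exposure`` a pollutant column entered
    linearly in ug/m3 after applying ``lag``.  ``time_control`` is either
    ``"strata"`` (case-crossover stratum indicators) or ``"spline"`` with
    ``time_spline_df_per_year`` df per year (the sensitivity configuration).
    A public-holiday indicator, if wanted, is passed as an extra covariate
    column; no holiday calendar is built in.
    """

    outcome: str
    exposure: str
    lag: LagSpec = LagSpec.moving_average(3)
    confounder_dfs: dict[str, int] = field(
        default_factory=lambda: {"temp_mean": 6, "rh": 3, "pressure": 3})
    extra_covariates: tuple[str, ...] = ("ili_daily",)
    copollutant: str | None = None
    time_control: str = "strata"
    time_spline_df_per_year: int = 7

    def __post_init__(self) -> None:
        if self.time_control not in ("strata", "spline"):
            raise ValueError(f"unknown time_control {self.time_control!r}")
        for name, df in self.confounder_dfs.items():
            if df < 1:
                raise ValueError(f"confounder df for {name!r} must be >= 1")

    @property
    def exposure_term(self) -> str:
        return f"{self.exposure}_{self.lag.name}"


@dataclass
class FitResult:
    """Fitted coefficients, dispersion-scaled covariance and the exposure term."""

    params: pd.Series
    cov: pd.DataFrame
    dispersion: float
    n_days: int
    exposure_term: str
    spec: ModelSpec
    converged: bool
    dropped_rows: int
    exposure_basis: SplineBasis | None = None

    @property
    def beta(self) -> float:
        return float(self.params[self.exposure_term])

    @property
    def se(self) -> float:
        return float(np.sqrt(self.cov.loc[self.exposure_term, self.exposure_term]))


@dataclass(frozen=True)
class EffectEstimate:
    """Percent change in mortality per ``delta`` ug/m3, with 95% CI."""

    percent: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    delta: float = 10.0


@dataclass
class ERCurve:
    """Exposure-response curve: log-RR over an exposure grid vs the minimum."""

    grid: np.ndarray
    log_rr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    df: int
    reference: float
    exposure_term: str


# ---------------------------------------------------------------------------
# Design-matrix assembly
# ---------------------------------------------------------------------------

def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [X.columns[i] for i in piv[rank:]]
        raise FitError(f"collinear design; aliased columns: {aliased}")


def _exposure_column(series: DailySeries, name: str, lag: LagSpec) -> pd.Series:
    col = apply_lag(series.frame[name], lag)
    col.name = f"{name}_{lag.name}"
    return col


def build_design(
    series: DailySeries,
    spec: ModelSpec,
    exposure_spline_df: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame, pd.DatetimeIndex, SplineBasis | None, int]:
    """Assemble outcome vector and design matrix for one regression.

    Rows with any missing model input (including the lag burn-in) are
    dropped (complete-case); strata whose outcome total is zero carry no
    information in a conditional design and are dropped too.
    Returns (y, X, used dates, exposure spline basis or None, dropped rows).
    """
    f = series.frame
    parts: dict[str, pd.Series] = {}
    exp_col = _exposure_column(series, spec.exposure, spec.lag)
    parts[exp_col.name] = exp_col
    if spec.copollutant is not None:
        co_col = _exposure_column(series, spec.copollutant, spec.lag)
        parts[co_col.name] = co_col
    for name in spec.extra_covariates:
        parts[name] = f[name]
    needed = [spec.outcome] + list(spec.confounder_dfs)
    raw = pd.DataFrame(parts, index=f.index).join(f[needed])

    keep = raw.notna().all(axis=1)
    if spec.time_control == "strata":
        strata = make_strata(f.index).labels
        totals = f[spec.outcome].groupby(strata).transform("sum")
        keep &= totals > 0
    used = f.index[keep]
    dropped = int(len(f) - keep.sum())
    if dropped:
        logger.info("dropped %d rows (burn-in/missing/empty strata)", dropped)
    raw = raw.loc[used]
    y = raw.pop(spec.outcome).to_numpy(dtype=float)

    X_parts: list[pd.DataFrame] = [
        pd.DataFrame({"intercept": np.ones(len(used))}, index=used)
    ]
    exposure_basis = None
    if exposure_spline_df is None:
        X_parts.append(raw[[exp_col.name]])
    else:
        exposure_basis = ns_basis(
            raw[exp_col.name], exposure_spline_df, column=exp_col.name
        )
        cols = {
            f"{exp_col.name}_ns{j + 1}": exposure_basis.matrix[:, j]
            for j in range(exposure_spline_df)
        }
        X_parts.append(pd.DataFrame(cols, index=used))
    if spec.copollutant is not None:
        X_parts.append(raw[[f"{spec.copollutant}_{spec.lag.name}"]])
    for name in spec.extra_covariates:
        X_parts.append(raw[[name]])
    for name, df in spec.confounder_dfs.items():
        basis = ns_basis(raw[name], df, column=name)
        cols = {f"{name}_ns{j + 1}": basis.matrix[:, j] for j in range(df)}
        X_parts.append(pd.DataFrame(cols, index=used))

    if spec.time_control == "strata":
        labels = make_strata(used).labels
        dummies = pd.get_dummies(labels, prefix="stratum", drop_first=True)
        X_parts.append(dummies.astype(float))
    else:
        n_years = max(1, round(len(f) / 365.25))
        time_df = spec.time_spline_df_per_year * n_years
        day_idx = pd.Series(
            (used - f.index[0]).days.to_numpy(dtype=float), index=used, name="time"
        )
        basis = ns_basis(day_idx, time_df, column="time")
        cols = {f"time_ns{j + 1}": basis.matrix[:, j] for j in range(time_df)}
        X_parts.append(pd.DataFrame(cols, index=used))

    X = pd.concat(X_parts, axis=1)
    return y, X, used, exposure_basis, dropped


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_quasipoisson(
    series: DailySeries,
    spec: ModelSpec,
    exposure_spline_df: int | None = None,
) -> FitResult:
    """Fit the quasi-Poisson model by IRLS.

    Point estimates are the Poisson maximum likelihood; the covariance is
    scaled by the Pearson dispersion phi = chi^2_P / (n - p), so standard
    errors absorb overdispersion.  Raises :class:`FitError` on a collinear
    design (naming the aliased columns) or non-convergence.
    """
    y, X, used, exposure_basis, dropped = build_design(
        series, spec, exposure_spline_df
    )
    n, p = X.shape
    if n <= p:
        raise FitError(f"design has more parameters ({p}) than days ({n})")
    _check_full_rank(X)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(scale="X2", maxiter=200)
    if not getattr(res, "converged", True):
        raise FitError(
            f"IRLS did not converge in {res.fit_history['iteration']} iterations; "
            f"deviance trace: {res.fit_history['deviance'][-5:]}"
        )
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return FitResult(
        params=pd.Series(res.params, index=X.columns),
        cov=cov,
        dispersion=float(res.scale),
        n_days=n,
        exposure_term=spec.exposure_term,
        spec=spec,
        converged=True,
        dropped_rows=dropped,
        exposure_basis=exposure_basis,
    )


def percent_change(beta: float, se: float, delta: float = 10.0) -> EffectEstimate:
    """Percent change in mortality per ``delta`` ug/m3: (exp(delta*beta)-1)*100.

    CI endpoints transform the beta-scale normal interval, so they are
    asymmetric around the point estimate on the percent scale.
    """
    if se < 0:
        raise ValueError("se must be >= 0")
    point = (np.exp(delta * beta) - 1.0) * 100.0
    low = (np.exp(delta * (beta - Z_95 * se)) - 1.0) * 100.0
    high = (np.exp(delta * (beta + Z_95 * se)) - 1.0) * 100.0
    return EffectEstimate(point, low, high, beta, se, delta)


def effect_from_fit(fit: FitResult, delta: float = 10.0) -> EffectEstimate:
    return percent_change(fit.beta, fit.se, delta)


def invert_percent_change(
    percent: float, ci_low: float, ci_high: float, delta: float = 10.0
) -> tuple[float, float]:
    """Back-solve (beta, se) from a reported percent change and its 95% CI."""
    beta = np.log(1.0 + percent / 100.0) / delta
    width = np.log(1.0 + ci_high / 100.0) - np.log(1.0 + ci_low / 100.0)
    se = width / (2.0 * Z_95 * delta)
    return float(beta), float(se)


# ---------------------------------------------------------------------------
# Lag profiling
# ---------------------------------------------------------------------------

@dataclass
class LagProfile:
    """Effect estimates across single lags plus the cumulative ma metric."""

    estimates: dict[str, EffectEstimate]
    errors: dict[str, str]

    def peak_single_lag(self) -> int:
        """Single lag with the largest point estimate."""
        singles = {
            int(k[3:]): v for k, v in self.estimates.items() if k.startswith("lag")
        }
        return max(singles, key=lambda k: singles[k].percent)


def lag_profile(
    series: DailySeries,
    spec: ModelSpec,
    max_lag: int = 10,
    include_ma: bool = True,
) -> LagProfile:
    """Fit one model per single lag 0..max_lag (plus ma03).

    Per-lag failures are recorded, not raised, so a degenerate metric cannot
    abort the profile.
    """
    lag_specs = [LagSpec.single(k) for k in range(max_lag + 1)]
    if include_ma:
        lag_specs.append(LagSpec.moving_average(3))
    estimates: dict[str, EffectEstimate] = {}
    errors: dict[str, str] = {}
    for ls in lag_specs:
        sub = replace(spec, lag=ls)
        try:
            estimates[ls.name] = effect_from_fit(fit_quasipoisson(series, sub))
        except (FitError, ValueError) as exc:
            errors[ls.name] = str(exc)
    return LagProfile(estimates=estimates, errors=errors)


# ---------------------------------------------------------------------------
# Exposure-response curve
# ---------------------------------------------------------------------------

def er_curve(
    series: DailySeries,
    spec: ModelSpec,
    df: int = 3,
    n_grid: int = 100,
) -> ERCurve:
    """Exposure-response curve with the exposure entered as a df-column spline.

    The curve is the fitted log relative risk on a grid spanning the observed
    (lagged) exposure, referenced to the observed minimum, with a pointwise
    95% band from the spline-coefficient covariance.  df=1 reduces the spline
    to the linear term, so the curve coincides with the log-linear fit.
    """
    if not 1 <= df <= 9:
        raise ValueError("df must be in 1..9")
    fit = fit_quasipoisson(series, spec, exposure_spline_df=df)
    basis = fit.exposure_basis
    assert basis is not None
    names = [f"{spec.exposure_term}_ns{j + 1}" for j in range(df)]
    theta = fit.params[names].to_numpy()
    cov = fit.cov.loc[names, names].to_numpy()

    lo, hi = basis.boundary_knots
    grid = np.linspace(lo, hi, n_grid)
    B = basis.evaluate(grid) - basis.evaluate(np.array([lo]))
    log_rr = B @ theta
    sd = np.sqrt(np.einsum("ij,jk,ik->i", B, cov, B))
    return ERCurve(
        grid=grid,
        log_rr=log_rr,
        ci_low=log_rr - Z_95 * sd,
        ci_high=log_rr + Z_95 * sd,
        df=df,
        reference=lo,
        exposure_term=spec.exposure_term,
    )


# ---------------------------------------------------------------------------
# Subgroup comparison and two-pollutant models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupComparison:
    z: float
    p_value: float


def compare_subgroups(e1: FitResult, e2: FitResult) -> SubgroupComparison:
    """Two-sample z test for the difference between two subgroup log-RRs.

    z = (b1 - b2) / sqrt(se1^2 + se2^2), p two-sided from the standard normal.
    """
    se1, se2 = e1.se, e2.se
    if se1 == 0.0 and se2 == 0.0:
        raise ValueError("both standard errors are zero; z undefined")
    z = (e1.beta - e2.beta) / np.sqrt(se1**2 + se2**2)
    p = 2.0 * stats.norm.sf(abs(z))
    return SubgroupComparison(z=float(z), p_value=float(p))


@dataclass
class ScreenResult:
    """Spearman collinearity screen over pollutant pairs."""

    rho: dict[tuple[str, str], float]
    admissible: list[tuple[str, str]]
    excluded: list[tuple[str, str]]
    skipped: list[tuple[str, str]]
    threshold: float

    def is_admissible(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in {tuple(sorted(p)) for p in self.admissible}


def collinearity_screen(
    series: DailySeries,
    pollutants: list[str] | None = None,
    threshold: float = 0.7,
) -> ScreenResult:
    """Spearman rank correlation between pollutant pairs; |rho| >= 0.7 excluded.

    Two-pollutant models are only admissible for pairs below the threshold,
    avoiding collinear co-adjustment.  Constant series are skipped with a
    warning.  Ties are handled with average ranks.
    """
    if pollutants is None:
        pollutants = series.exposure_columns
    if len(pollutants) < 2:
        raise ValueError("need at least two pollutants to screen")
    rho: dict[tuple[str, str], float] = {}
    admissible, excluded, skipped = [], [], []
    for i, a in enumerate(pollutants):
        for b in pollutants[i + 1 :]:
            xa, xb = series.frame[a], series.frame[b]
            if xa.nunique() <= 1 or xb.nunique() <= 1:
                logger.warning("constant series in pair (%s, %s); skipped", a, b)
                skipped.append((a, b))
                continue
            r = float(stats.spearmanr(xa, xb, nan_policy="omit").statistic)
            rho[(a, b)] = r
            if abs(r) >= threshold:
                excluded.append((a, b))
                logger.info("pair (%s, %s) excluded: |rho|=%.3f", a, b, abs(r))
            else:
                admissible.append((a, b))
    return ScreenResult(rho, admissible, excluded, skipped, threshold)


def fit_two_pollutant(
    series: DailySeries,
    spec: ModelSpec,
    copollutant: str,
    screen: ScreenResult | None = None,
) -> FitResult:
    """Fit with a co-pollutant added linearly under the same lag metric.

    Refuses pairs that fail the Spearman screen, citing the correlation.
    """
    if screen is None:
        screen = collinearity_screen(series, [spec.exposure, copollutant])
    if not screen.is_admissible(spec.exposure, copollutant):
        key = tuple(sorted((spec.exposure, copollutant)))
        r = screen.rho.get(key, screen.rho.get(key[::-1], float("nan")))
        raise ValueError(
            f"pair ({spec.exposure}, {copollutant}) fails the collinearity "
            f"screen: |Spearman rho| = {abs(r):.3f} >= {screen.threshold}"
        )
    return fit_quasipoisson(series, replace(spec, copollutant=copollutant))
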