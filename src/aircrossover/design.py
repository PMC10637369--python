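"""Right-hand-side building blocks for the case-crossover regression.

Three ingredients: time strata (year x month x day-of-week, the standard
referent scheme of the time-stratified case-crossover design), natural
cubic spline bases for confounder adjustment, and single-lag /
moving-average exposure metrics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Time strata
# ---------------------------------------------------------------------------

@dataclass
class StrataAssignment:
    """Per-day stratum labels of the form ``YYYY-MM:wd``.

    Days sharing calendar year, month and weekday share a stratum, so each
    stratum holds the 4-5 same-weekday days of one month; comparisons within
    it are self-controlled for season, trend and day of week.  Strata of a
    single day carry no within-stratum contrast and are flagged.
    """

    labels: pd.Series
    singletons: list[str] = field(default_factory=list)

    @property
    def n_strata(self) -> int:
        return self.labels.nunique()


def make_strata(dates: pd.DatetimeIndex) -> StrataAssignment:
    """Assign every day to its (year, month, weekday) stratum."""
    labels = pd.Series(
        [f"{d.year:04d}-{d.month:02d}:{d.dayofweek}" for d in dates],
        index=dates,
        name="stratum",
    )
    counts = labels.value_counts()
    singletons = sorted(counts.index[counts == 1])
    return StrataAssignment(labels=labels, singletons=singletons)


# ---------------------------------------------------------------------------
# Natural cubic splines
# ---------------------------------------------------------------------------

@dataclass
class SplineBasis:
    """Evaluated natural cubic spline basis for one input column.

    ``df`` columns; interior knots at equally spaced quantiles of the input,
    boundary knots at the data range (or a supplied boundary).  The basis
    spans linear functions exactly and is linear beyond the boundary knots.
    """

    column: str
    df: int
    interior_knots: np.ndarray
    boundary_knots: tuple[float, float]
    matrix: np.ndarray

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the same basis functions at new points."""
        return _ns_matrix(
            np.asarray(x, dtype=float), self.interior_knots, self.boundary_knots
        )


def _ns_matrix(
    x: np.ndarray, interior: np.ndarray, boundary: tuple[float, float]
) -> np.ndarray:
    """Natural cubic spline basis (truncated-power construction).

    With K knots (boundary + interior) the natural spline space, excluding
    the constant, has dimension K-1: the identity plus K-2 functions
    d_k(x) - d_{K-1}(x) where d_k(x) = ((x-k_k)+^3 - (x-k_K)+^3)/(k_K - k_k).
    """
    lo, hi = boundary
    knots = np.sort(np.concatenate([[lo], np.asarray(interior, float), [hi]]))
    K = len(knots)

    def d(k_idx: int) -> np.ndarray:
        num = np.clip(x - knots[k_idx], 0, None) ** 3 - np.clip(
            x - knots[K - 1], 0, None
        ) ** 3
        return num / (knots[K - 1] - knots[k_idx])

    cols = [x]
    if K > 2:
        d_last = d(K - 2)
        cols.extend(d(k) - d_last for k in range(K - 2))
    return np.column_stack(cols)


def ns_basis(
    x: pd.Series | np.ndarray,
    df: int,
    boundary: tuple[float, float] | None = None,
    column: str = "x",
) -> SplineBasis:
    """Natural cubic spline basis with ``df`` columns.

    Interior knots sit at the quantiles i/df (i = 1..df-1) of ``x``;
    boundary knots at the observed range unless ``boundary`` is given.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    name = x.name if isinstance(x, pd.Series) and x.name else column
    arr = np.asarray(x, dtype=float)
    finite = arr[np.isfinite(arr)]
    if len(np.unique(finite)) < df + 1:
        raise ValueError(
            f"column {name!r} has fewer than df+1={df + 1} distinct values"
        )
    if boundary is None:
        boundary = (float(finite.min()), float(finite.max()))
    probs = np.arange(1, df) / df
    interior = np.quantile(finite, probs) if df > 1 else np.array([])
    return SplineBasis(
        column=name,
        df=df,
        interior_knots=np.asarray(interior, float),
        boundary_knots=boundary,
        matrix=_ns_matrix(arr, interior, boundary),
    )


# ---------------------------------------------------------------------------
# Lag metrics
# ---------------------------------------------------------------------------

_LAG_RE = re.compile(r"^lag(\d+)$")
_MA_RE = re.compile(r"^ma0(\d+)$")


@dataclass(frozen=True)
class LagSpec:
    """Exposure lag metric: a single lag k, or the moving average of lags 0..k."""

    kind: str  # "single" | "ma"
    lags: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("single", "ma"):
            raise ValueError(f"unknown lag kind {self.kind!r}")
        if any(l < 0 for l in self.lags):
            raise ValueError("lags must be nonnegative")
        if self.kind == "single" and len(self.lags) != 1:
            raise ValueError("single-lag spec takes exactly one lag")
        if self.kind == "ma" and tuple(self.lags) != tuple(range(len(self.lags))):
            raise ValueError("moving-average lags must be contiguous from 0")

    @property
    def max_lag(self) -> int:
        return max(self.lags)

    @property
    def name(self) -> str:
        if self.kind == "single":
            return f"lag{self.lags[0]}"
        return f"ma0{self.max_lag}"

    @classmethod
    def single(cls, k: int) -> "LagSpec":
        return cls("single", (k,))

    @classmethod
    def moving_average(cls, max_lag: int) -> "LagSpec":
        return cls("ma", tuple(range(max_lag + 1)))

    @classmethod
    def parse(cls, text: str) -> "LagSpec":
        """Parse pipeline-config strings like ``"lag2"`` or ``"ma03"``."""
        m = _LAG_RE.match(text)
        if m:
            return cls.single(int(m.group(1)))
        m = _MA_RE.match(text)
        if m:
            return cls.moving_average(int(m.group(1)))
        raise ValueError(f"unrecognised lag spec {text!r}")


def apply_lag(exposure: pd.Series, spec: LagSpec) -> pd.Series:
    """Apply a lag metric; the first ``max_lag`` days come back as NaN.

    A single lag k shifts the series by k days; a moving average 0..k
    returns the mean of the current and the k preceding days.
    """
    if spec.max_lag >= len(exposure):
        raise ValueError(
            f"max lag {spec.max_lag} >= series length {len(exposure)}"
        )
    if spec.kind == "single":
        return exposure.shift(spec.lags[0])
    window = spec.max_lag + 1
    return exposure.rolling(window=window, min_periods=window).mean()
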