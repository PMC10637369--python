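"""Daily time-series data model and CSV input/output.

The whole pipeline operates on a single tabular currency: one row per
calendar day carrying pollutant concentrations, meteorology, a daily
influenza-like-illness (ILI) covariate, and death counts per cause or
stratum.  Death-count columns are prefixed ``deaths_``; all other column
names are fixed by :data:`POLLUTANT_COLUMNS` and :data:`MET_COLUMNS`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Pollutant columns, concentrations in ug/m3 except carbon monoxide (mg/m3).
POLLUTANT_COLUMNS = ["pm1", "pm25", "pm10", "o3", "so2", "no2", "co"]

#: Meteorology columns: temperatures in degC, relative humidity %, pressure hPa.
MET_COLUMNS = ["temp_mean", "temp_min", "temp_max", "rh", "pressure"]

ILI_COLUMN = "ili_daily"

DEATHS_PREFIX = "deaths_"


class SeriesValidationError(ValueError):
    """Raised when a daily series violates the data-model invariants."""


@dataclass(frozen=True)
class CauseEntry:
    """One outcome cause: its deaths column and ICD-10 range annotation."""

    column: str
    icd_range: str = ""


@dataclass
class CauseTable:
    """Mapping of cause names to death-count columns.

    Cause categories are pre-aggregated daily counts; the ICD-10 range is
    carried as documentation only (e.g. nonaccidental = A00-R99).
    """

    entries: dict[str, CauseEntry] = field(default_factory=dict)

    def column(self, cause: str) -> str:
        return self.entries[cause].column

    @property
    def causes(self) -> list[str]:
        return list(self.entries)

    def validate_against(self, columns: list[str]) -> None:
        missing = [e.column for e in self.entries.values() if e.column not in columns]
        if missing:
            raise SeriesValidationError(
                f"cause table references absent death columns: {missing}"
            )


#: Default cause schema mirroring a registry aggregated by broad ICD-10 chapter.
DEFAULT_CAUSES = CauseTable(
    {
        "all_cause": CauseEntry("deaths_all_cause", "A00-Z99"),
        "nonaccidental": CauseEntry("deaths_nonaccidental", "A00-R99"),
        "circulatory": CauseEntry("deaths_circulatory", "I00-I99"),
        "respiratory": CauseEntry("deaths_respiratory", "J00-J99"),
        "neoplasms": CauseEntry("deaths_neoplasms", "C00-D48"),
    }
)


@dataclass
class DailySeries:
    """Aligned daily records of exposures, meteorology, ILI and outcomes.

    ``frame`` is indexed by a contiguous daily ``DatetimeIndex`` named
    ``date``.  ``metadata`` is free-form provenance; the synthetic-data
    generator records its ground-truth coefficients there.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        idx = self.frame.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise SeriesValidationError("index must be a DatetimeIndex of dates")
        if len(idx) == 0:
            raise SeriesValidationError("series is empty")
        expected = pd.date_range(idx[0], idx[-1], freq="D")
        if len(expected) != len(idx) or not (expected == idx).all():
            missing = expected.difference(idx)
            raise SeriesValidationError(
                "dates are not contiguous; missing: "
                + ", ".join(d.strftime("%Y-%m-%d") for d in missing[:10])
            )
        for col in self.death_columns:
            vals = self.frame[col]
            bad = vals.isna() | (vals < 0) | (vals != np.floor(vals.fillna(-1)))
            if bad.any():
                day = self.frame.index[bad.to_numpy()][0]
                raise SeriesValidationError(
                    f"column {col!r} has a non-count value on {day.date()}"
                )
        if "rh" in self.frame:
            rh = self.frame["rh"].dropna()
            if ((rh < 0) | (rh > 100)).any():
                raise SeriesValidationError("relative humidity outside [0, 100]")
        for col in POLLUTANT_COLUMNS:
            if col in self.frame and (self.frame[col].dropna() < 0).any():
                raise SeriesValidationError(f"negative exposure in column {col!r}")

    # -- convenience --------------------------------------------------------
    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def n_days(self) -> int:
        return len(self.frame)

    @property
    def death_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith(DEATHS_PREFIX)]

    @property
    def exposure_columns(self) -> list[str]:
        return [c for c in POLLUTANT_COLUMNS if c in self.frame.columns]

    def subset(self, mask: pd.Series) -> "DailySeries":
        """Return a new series restricted to ``mask`` days.

        The restriction may break date contiguity (season subsets do), so the
        result bypasses the contiguity check but keeps everything else.
        """
        sub = DailySeries.__new__(DailySeries)
        sub.frame = self.frame.loc[mask].copy()
        sub.metadata = dict(self.metadata)
        return sub


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_daily_series(series: DailySeries, path: str | Path) -> None:
    """Write the series as a one-row-per-day CSV plus a JSON metadata sidecar."""
    path = Path(path)
    out = series.frame.copy()
    out.index.name = "date"
    out.to_csv(path, date_format="%Y-%m-%d")
    if series.metadata:
        _meta_path(path).write_text(json.dumps(series.metadata, indent=1, default=str))


def read_daily_series(path: str | Path, schema: CauseTable | None = None) -> DailySeries:
    """Read and validate a daily-series CSV.

    Date gaps, negative/non-integer counts and out-of-range humidity are
    errors; unknown columns are carried through with a logged warning.
    Per-column missing-value counts are recorded in ``metadata['missing']``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, parse_dates=["date"], index_col="date")

    known = set(POLLUTANT_COLUMNS) | set(MET_COLUMNS) | {ILI_COLUMN}
    unknown = [
        c for c in frame.columns if c not in known and not c.startswith(DEATHS_PREFIX)
    ]
    if unknown:
        logger.warning("unknown columns carried through unvalidated: %s", unknown)

    metadata: dict = {}
    mp = _meta_path(path)
    if mp.exists():
        metadata = json.loads(mp.read_text())
    metadata["missing"] = {
        c: int(frame[c].isna().sum()) for c in frame.columns if frame[c].isna().any()
    }

    series = DailySeries(frame, metadata)
    if schema is not None:
        schema.validate_against(list(frame.columns))
    return series


def weekly_to_daily_ili(
    weekly_counts: pd.Series, dates: pd.DatetimeIndex
) -> pd.Series:
    """Spread weekly ILI counts uniformly over the days of each week.

    ``weekly_counts`` is indexed by week start dates; week *i* covers the
    seven days from its start.  Each covered day receives ``count / 7`` so
    the weekly total is conserved.  Days of ``dates`` not covered by any
    week are an error.
    """
    starts = pd.DatetimeIndex(weekly_counts.index)
    daily = pd.Series(np.nan, index=dates, dtype=float)
    for start, count in zip(starts, weekly_counts.to_numpy()):
        week_days = pd.date_range(start, periods=7, freq="D")
        hit = dates.intersection(week_days)
        daily.loc[hit] = count / 7.0
    if daily.isna().any():
        uncovered = dates[daily.isna().to_numpy()]
        raise ValueError(
            "days not covered by any ILI week: "
            + ", ".join(d.strftime("%Y-%m-%d") for d in uncovered[:10])
        )
    return daily
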