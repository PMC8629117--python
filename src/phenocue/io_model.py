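"""Input handling for phenology and daily-climate tables.

Two CSV layouts are supported: an annual phenology table (one row per
year, mean event date in days since 1 April) and a daily climate table
(one row per calendar day, daily mean temperature in °C).  This module
validates both, applies the standard data-preparation rules (late-record
exclusion, whole-day rounding) and builds the lag-indexed climate matrix
that the calendar-anchored methods share.

Conventions
-----------
* Event days count from 1 April: 1 April = day 1.
* The reference day anchoring absolute lag indices defaults to 20 May.
* Lag ``d`` means the calendar day ``d`` days before the reference day,
  walking back through real dates (leap days are neither skipped nor
  duplicated).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Day-of-event origin: 1 April = day 1.
DAY_ORIGIN_MONTH, DAY_ORIGIN_DAY = 4, 1

#: Default calendar anchor for absolute lag indexing (month, day).
DEFAULT_REFERENCE_DAY = (5, 20)

#: Records later than first record + this many days are treated as
#: second/replacement attempts and excluded from annual means.
LATE_RECORD_CUTOFF = 30


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class CoverageError(ValueError):
    """Raised when the climate series does not cover a required day."""


def event_day_to_date(year: int, event_day: int) -> dt.date:
    """Convert a day-since-1-April index to a calendar date."""
    return dt.date(year, DAY_ORIGIN_MONTH, DAY_ORIGIN_DAY) + dt.timedelta(
        days=int(event_day) - 1
    )


def date_to_event_day(date: dt.date) -> int:
    """Convert a calendar date to days since 1 April of its year."""
    origin = dt.date(date.year, DAY_ORIGIN_MONTH, DAY_ORIGIN_DAY)
    return (date - origin).days + 1


def round_half_up(x) -> np.ndarray:
    """Round to the nearest whole day, halves away from zero."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class PhenologySeries:
    """Annual mean event dates.

    Attributes
    ----------
    years : ndarray of int
        Strictly increasing calendar years, no duplicates.
    event_day : ndarray of int
        Mean event date per year, whole days since 1 April (1 April = 1).
    """

    years: np.ndarray
    event_day: np.ndarray
    bounds: tuple[int, int] = (1, 120)

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        days = np.asarray(np.rint(self.event_day), dtype=int)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "event_day", days)
        if years.shape != days.shape or years.ndim != 1:
            raise ValidationError("years and event_day must be 1-d and aligned")
        uniq, counts = np.unique(years, return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1]
            raise ValidationError(f"duplicate year(s) in phenology series: {dup.tolist()}")
        if not np.all(np.diff(years) > 0):
            raise ValidationError("years must be strictly increasing")
        lo, hi = self.bounds
        bad = (days < lo) | (days > hi)
        if bad.any():
            raise ValidationError(
                f"event day outside bounds [{lo}, {hi}] for year(s) "
                f"{years[bad].tolist()} (values {days[bad].tolist()})"
            )

    def __len__(self) -> int:
        return len(self.years)

    def subset(self, year_lo: int, year_hi: int) -> "PhenologySeries":
        """Rows with ``year_lo <= year <= year_hi`` (inclusive)."""
        m = (self.years >= year_lo) & (self.years <= year_hi)
        return PhenologySeries(self.years[m], self.event_day[m], self.bounds)

    def select(self, years) -> "PhenologySeries":
        """Rows for an explicit list of years (order as stored)."""
        years = set(int(y) for y in years)
        m = np.array([int(y) in years for y in self.years])
        return PhenologySeries(self.years[m], self.event_day[m], self.bounds)

    def event_dates(self) -> list[dt.date]:
        return [event_day_to_date(y, d) for y, d in zip(self.years, self.event_day)]

    def to_frame(self) -> pd.DataFrame:
        dates = self.event_dates()
        return pd.DataFrame(
            {
                "year": self.years,
                "event_day": self.event_day,
                "date": [d.strftime("%d/%m/%Y") for d in dates],
                "day_of_month": [d.day for d in dates],
                "month": [d.month for d in dates],
                "day_of_year": [d.timetuple().tm_yday for d in dates],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ClimateSeries:
    """Contiguous daily mean temperatures (°C), one record per day."""

    temps: pd.Series  # float values indexed by a daily DatetimeIndex

    def __post_init__(self):
        s = self.temps
        if not isinstance(s.index, pd.DatetimeIndex):
            raise ValidationError("climate series must be indexed by date")
        if s.index.has_duplicates:
            raise ValidationError("duplicate dates in climate series")
        if not s.index.is_monotonic_increasing:
            s = s.sort_index()
            object.__setattr__(self, "temps", s)
        if not np.isfinite(s.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite temperature values")
        full = pd.date_range(s.index[0], s.index[-1], freq="D")
        if len(full) != len(s):
            missing = full.difference(s.index)
            raise ValidationError(
                f"climate series has gaps; first missing day: {missing[0].date()}"
            )

    def __len__(self) -> int:
        return len(self.temps)

    @property
    def start(self) -> dt.date:
        return self.temps.index[0].date()

    @property
    def end(self) -> dt.date:
        return self.temps.index[-1].date()

    def temp_on(self, dates) -> np.ndarray:
        """Temperatures for the given dates; raises if any are missing."""
        idx = pd.DatetimeIndex(pd.to_datetime(list(np.atleast_1d(dates))))
        vals = self.temps.reindex(idx)
        if vals.isna().any():
            missing = idx[vals.isna().to_numpy()][0].date()
            raise CoverageError(f"climate series does not cover {missing}")
        return vals.to_numpy(dtype=float)

    def year_day_matrix(self, years) -> np.ndarray:
        """(len(years), 366) array of temps indexed by day of year (NaN-padded)."""
        out = np.full((len(years), 366), np.nan)
        for i, y in enumerate(years):
            sel = self.temps[str(int(y))]
            doy = sel.index.dayofyear.to_numpy() - 1
            out[i, doy] = sel.to_numpy(dtype=float)
        return out

    def to_frame(self) -> pd.DataFrame:
        idx = self.temps.index
        return pd.DataFrame(
            {
                "date": idx.strftime("%d/%m/%Y"),
                "day_of_month": idx.day,
                "month": idx.month,
                "day_of_year": idx.dayofyear,
                "temperature": self.temps.to_numpy(dtype=float),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ClimateMatrix:
    """Years × lag-days matrix of daily mean temperature.

    ``values[i, j]`` is the temperature on the day ``lags[j]`` days before
    ``reference_day`` of ``years[i]``.  Lags are counted back through real
    calendar dates, so a 365-lag walk crosses 29 February when present.
    """

    years: np.ndarray
    lags: np.ndarray
    values: np.ndarray
    reference_day: tuple[int, int] = DEFAULT_REFERENCE_DAY

    def __post_init__(self):
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "lags", np.asarray(self.lags, dtype=int))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.years), len(self.lags)):
            raise ValidationError("climate matrix shape mismatch")

    def value(self, year: int, lag: int) -> float:
        i = int(np.flatnonzero(self.years == year)[0])
        j = int(np.flatnonzero(self.lags == lag)[0])
        return float(self.values[i, j])

    def select_years(self, years) -> "ClimateMatrix":
        wanted = [int(y) for y in years]
        pos = {int(y): i for i, y in enumerate(self.years)}
        missing = [y for y in wanted if y not in pos]
        if missing:
            raise ValidationError(f"matrix does not contain year(s) {missing}")
        idx = [pos[y] for y in wanted]
        return ClimateMatrix(
            np.array(wanted), self.lags, self.values[idx], self.reference_day
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"d{lag}" for lag in self.lags]
        )
        df.insert(0, "year", self.years)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class NestRecordSet:
    """Individual event records (one per nest), used to form annual means."""

    years: np.ndarray
    lay_day: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "lay_day", np.asarray(self.lay_day, dtype=float))
        if self.years.shape != self.lay_day.shape or self.years.ndim != 1:
            raise ValidationError("years and lay_day must be 1-d and aligned")
        if len(self.years) == 0:
            raise ValidationError("empty nest record set")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_PHENOLOGY_DAY_NAMES = (
    "event_day",
    "mean_lay_date",
    "lay_date",
    "days_since_1_april",
    "mean lay date (in days since 1 april)",
)


def _normalise(name: str) -> str:
    return name.strip().lower().replace("-", "_").replace(" ", "_")


def _parse_dates(col: pd.Series) -> pd.DatetimeIndex:
    """Accept ISO-8601 (yyyy-mm-dd) or dd/mm/yyyy dates."""
    sample = str(col.iloc[0])
    fmt = "%Y-%m-%d" if "-" in sample else "%d/%m/%Y"
    return pd.DatetimeIndex(pd.to_datetime(col, format=fmt))


def read_phenology(path, bounds: tuple[int, int] = (1, 120)) -> PhenologySeries:
    """Read and validate an annual phenology CSV.

    The file needs a ``year`` column and a mean-event-day column (days
    since 1 April); extra columns (calendar date, month, day of year) are
    ignored.  Non-integer event days are rounded to the nearest whole day.
    """
    df = pd.read_csv(path)
    cols = {_normalise(c): c for c in df.columns}
    if "year" not in cols:
        raise ValidationError(f"{path}: no 'year' column (found {list(df.columns)})")
    day_col = next((cols[n] for n in _PHENOLOGY_DAY_NAMES if n in cols), None)
    if day_col is None:
        # fall back to the first non-year numeric column
        numeric = [
            c
            for c in df.columns
            if c != cols["year"] and pd.api.types.is_numeric_dtype(df[c])
        ]
        if not numeric:
            raise ValidationError(f"{path}: no event-day column found")
        day_col = numeric[0]
    years = df[cols["year"]].to_numpy(dtype=int)
    days = round_half_up(df[day_col].to_numpy(dtype=float)).astype(int)
    order = np.argsort(years, kind="stable")
    return PhenologySeries(years[order], days[order], bounds)


def read_climate(path) -> ClimateSeries:
    """Read and validate a daily climate CSV (date + temperature columns)."""
    df = pd.read_csv(path)
    cols = {_normalise(c): c for c in df.columns}
    if "date" not in cols:
        raise ValidationError(f"{path}: no 'date' column")
    temp_col = next(
        (cols[n] for n in ("temperature", "temp", "mean_temperature", "temperature_c")
         if n in cols),
        None,
    )
    if temp_col is None:
        raise ValidationError(f"{path}: no temperature column")
    idx = _parse_dates(df[cols["date"]].astype(str))
    s = pd.Series(df[temp_col].to_numpy(dtype=float), index=idx).sort_index()
    return ClimateSeries(s)


# ---------------------------------------------------------------------------
# preparation rules
# ---------------------------------------------------------------------------

def annual_means_from_nests(records: NestRecordSet) -> PhenologySeries:
    """Annual means after excluding presumed second/replacement attempts.

    Within each year, records more than :data:`LATE_RECORD_CUTOFF` days
    after the first (earliest) record are dropped — strictly more than, so
    a record exactly 30 days after the first is retained.  The mean of the
    survivors is rounded to the nearest whole day.  Idempotent on already
    filtered data.
    """
    years = np.unique(records.years)
    means = np.empty(len(years))
    for i, y in enumerate(years):
        days = records.lay_day[records.years == y]
        keep = days <= days.min() + LATE_RECORD_CUTOFF
        means[i] = days[keep].mean()
    days = round_half_up(means).astype(int)
    lo = min(1, int(days.min()))
    hi = max(120, int(days.max()))
    return PhenologySeries(years, days, (lo, hi))


def build_climate_matrix(
    climate: ClimateSeries,
    years,
    reference_day: tuple[int, int] = DEFAULT_REFERENCE_DAY,
    include_reference_day: bool = True,
    n_lags: int = 365,
) -> ClimateMatrix:
    """Build the years × lag-days temperature matrix.

    Parameters
    ----------
    include_reference_day
        If True the lag axis is 0..n_lags-1 with lag 0 = the reference day
        itself; if False it is 1..n_lags (starting the day before the
        reference day, the convention of the day-by-day sensitivity
        profile).
    """
    years = np.asarray(list(years), dtype=int)
    month, day = reference_day
    first_lag = 0 if include_reference_day else 1
    lags = np.arange(first_lag, first_lag + n_lags)
    values = np.empty((len(years), n_lags))
    for i, y in enumerate(years):
        ref = dt.date(int(y), month, day)
        dates = [ref - dt.timedelta(days=int(lag)) for lag in lags]
        try:
            values[i] = climate.temp_on(dates)
        except CoverageError as exc:
            raise CoverageError(f"year {y}: {exc}") from None
    return ClimateMatrix(years, lags, values, reference_day)
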