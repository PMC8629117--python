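"""Exhaustive sliding-time-window search for temperature cues.

Two framings are provided.  The *absolute* search (SWA) scores windows
anchored to a fixed calendar reference day (default 20 May), so a window
is the same span of calendar days every year.  The *relative* search
(SWR) anchors windows to each year's phenological event, so a window is
a fixed lag before the event but covers different calendar days each
year.  Every (open, close) pair up to a maximum duration is scored with
each requested aggregate statistic (mean, min, max, within-window
slope), ranked by AICc against the intercept-only baseline.

Only absolute-frame cues support prediction: a relative window cannot be
located until the event it is meant to predict has happened.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import regression_core as rc
from .io_model import (
    ClimateMatrix,
    ClimateSeries,
    PhenologySeries,
    ValidationError,
    event_day_to_date,
)

STATISTICS = ("mean", "min", "max", "slope")

#: AICc differences below this are treated as ties for ranking purposes.
AICC_TIE_TOL = 1e-8


@dataclass(frozen=True)
class WindowSpec:
    """A candidate window: lags `close..open` days before the anchor."""

    open: int
    close: int
    frame: str = "absolute"  # 'absolute' (calendar anchor) or 'relative' (event anchor)
    statistic: str = "mean"

    def __post_init__(self):
        if self.frame not in ("absolute", "relative"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if not (self.open >= self.close >= 0):
            raise ValueError(
                f"need open >= close >= 0, got open={self.open} close={self.close}"
            )

    @property
    def duration(self) -> int:
        return self.open - self.close + 1


@dataclass(frozen=True)
class CandidateResult:
    window: WindowSpec
    fit: rc.LinearFit
    aicc: float
    delta_aicc: float


@dataclass(frozen=True)
class CueModel:
    """A fitted cue→phenology line tied to a specific window."""

    window: WindowSpec
    fit: rc.LinearFit
    training_years: tuple[int, int]
    reference_day: tuple[int, int] = (5, 20)


@dataclass
class WindowSearchResult:
    """Full ranked candidate table plus the baseline AICc.

    ``table`` columns: statistic, open, close, duration, intercept,
    slope, slope_se, r2, r2_adj, rss, sigma2, sxx, x_mean, aicc,
    delta_aicc — one row per scored candidate, ranked best first.
    """

    table: pd.DataFrame
    baseline_aicc: float
    frame: str
    training_years: tuple[int, int]
    reference_day: tuple[int, int]
    n_years: int

    def candidate(self, i: int = 0) -> CandidateResult:
        row = self.table.iloc[i]
        window = WindowSpec(
            int(row["open"]), int(row["close"]), self.frame, str(row["statistic"])
        )
        fit = rc.LinearFit(
            intercept=float(row["intercept"]),
            slope=float(row["slope"]),
            slope_se=float(row["slope_se"]),
            r2=float(row["r2"]),
            r2_adj=float(row["r2_adj"]),
            n=self.n_years,
            sigma2=float(row["sigma2"]),
            x_mean=float(row["x_mean"]),
            sxx=float(row["sxx"]),
            rss=float(row["rss"]),
        )
        return CandidateResult(window, fit, float(row["aicc"]), float(row["delta_aicc"]))

    @property
    def best(self) -> CandidateResult:
        return self.candidate(0)

    def best_model(self) -> CueModel:
        c = self.best
        return CueModel(c.window, c.fit, self.training_years, self.reference_day)


# ---------------------------------------------------------------------------
# aggregates
# ---------------------------------------------------------------------------

def aggregate(temps, statistic: str) -> float:
    """Aggregate a window's daily temperatures (ordered oldest → newest).

    ``slope`` is the OLS gradient of temperature against within-window
    day index (°C per day; positive = warming toward the event) and
    requires at least two days.
    """
    temps = np.asarray(temps, dtype=float)
    if temps.ndim != 1 or len(temps) == 0:
        raise ValueError("window must contain at least one value")
    if statistic == "mean":
        return float(temps.mean())
    if statistic == "min":
        return float(temps.min())
    if statistic == "max":
        return float(temps.max())
    if statistic == "slope":
        m = len(temps)
        if m < 2:
            raise ValueError("slope aggregate undefined on a 1-day window")
        i = np.arange(m, dtype=float)
        return float(np.polyfit(i, temps, 1)[0])
    raise ValueError(f"unknown statistic {statistic!r}")


def _enumerate_windows(n_lags: int, max_duration: int):
    """(open_idx, close_idx) position pairs, grouped by close then open."""
    D = min(max_duration, n_lags)
    closes, opens = [], []
    for c in range(n_lags):
        top = min(c + D, n_lags)
        o = np.arange(c, top)
        opens.append(o)
        closes.append(np.full(len(o), c))
    return np.concatenate(opens), np.concatenate(closes)


def _window_aggregates(values: np.ndarray, o_idx, c_idx, statistic: str,
                       max_duration: int):
    """Aggregate ``values`` (years × lags, lag ascending) for every candidate.

    Candidate j covers lag positions c_idx[j]..o_idx[j].  Position order
    is *lag ascending*, i.e. newest → oldest; within-window slope is
    computed oldest → newest.
    """
    n_years, L = values.shape
    dur = o_idx - c_idx + 1
    if statistic == "mean":
        cs = np.concatenate(
            [np.zeros((n_years, 1)), np.cumsum(values, axis=1)], axis=1
        )
        return (cs[:, o_idx + 1] - cs[:, c_idx]) / dur
    if statistic in ("min", "max"):
        op = np.minimum if statistic == "min" else np.maximum
        D = min(max_duration, L)
        X = np.empty((n_years, len(o_idx)))
        j0 = 0
        for c in range(L):
            block = op.accumulate(values[:, c : min(c + D, L)], axis=1)
            X[:, j0 : j0 + block.shape[1]] = block
            j0 += block.shape[1]
        assert j0 == len(o_idx)
        return X
    if statistic == "slope":
        # slope of temp against day-in-window, oldest first: day index
        # i = o - j for lag position j in [c, o].
        cs = np.concatenate(
            [np.zeros((n_years, 1)), np.cumsum(values, axis=1)], axis=1
        )
        wj = values * np.arange(L)
        cw = np.concatenate([np.zeros((n_years, 1)), np.cumsum(wj, axis=1)], axis=1)
        S = cs[:, o_idx + 1] - cs[:, c_idx]           # Σ T
        SW = cw[:, o_idx + 1] - cw[:, c_idx]          # Σ j·T
        m = dur.astype(float)
        num = (o_idx - (m - 1.0) / 2.0) * S - SW      # Σ (i - ī)(T - T̄)
        den = m * (m**2 - 1.0) / 12.0                 # Σ (i - ī)²
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den > 0, num / den, np.nan)
    raise ValueError(f"unknown statistic {statistic!r}")


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def _rank(table: pd.DataFrame) -> pd.DataFrame:
    """Rank candidates: AICc ascending; ties (within 1e-8) prefer shorter
    duration, then smaller close (nearer the anchor), then statistic name."""
    key = np.round(table["aicc"].to_numpy() / AICC_TIE_TOL) * AICC_TIE_TOL
    order = np.lexsort(
        (
            table["statistic"].to_numpy(),
            table["close"].to_numpy(),
            table["duration"].to_numpy(),
            key,
        )
    )
    return table.iloc[order].reset_index(drop=True)


def _search_matrix(
    y: np.ndarray,
    values: np.ndarray,
    lags: np.ndarray,
    statistics,
    max_duration: int,
) -> tuple[pd.DataFrame, float]:
    n_years, L = values.shape
    o_idx, c_idx = _enumerate_windows(L, max_duration)
    baseline = rc.aicc_intercept_only(y)
    pieces = []
    for stat in statistics:
        if stat not in STATISTICS:
            raise ValueError(f"unknown statistic {stat!r}")
        oo, cc = o_idx, c_idx
        if stat == "slope":  # 1-day windows have no defined gradient
            keep = oo != cc
            oo, cc = oo[keep], cc[keep]
        X = _window_aggregates(values, oo, cc, stat, max_duration)
        fits = rc.fit_linear_many(X, y)
        df = pd.DataFrame(fits)
        df.insert(0, "statistic", stat)
        df.insert(1, "open", lags[oo])
        df.insert(2, "close", lags[cc])
        df.insert(3, "duration", oo - cc + 1)
        pieces.append(df)
    table = pd.concat(pieces, ignore_index=True)
    table["delta_aicc"] = table["aicc"] - baseline
    return _rank(table), baseline


def search_absolute(
    phenology: PhenologySeries,
    matrix: ClimateMatrix,
    statistics=STATISTICS,
    max_duration: int = 365,
) -> WindowSearchResult:
    """Exhaustive absolute-frame window search over a climate matrix."""
    if len(phenology) < 4:
        raise ValidationError("need at least 4 years for a window search")
    if not np.array_equal(phenology.years, matrix.years):
        matrix = matrix.select_years(phenology.years)
    y = phenology.event_day.astype(float)
    table, baseline = _search_matrix(
        y, matrix.values, matrix.lags, statistics, max_duration
    )
    return WindowSearchResult(
        table,
        baseline,
        "absolute",
        (int(phenology.years.min()), int(phenology.years.max())),
        matrix.reference_day,
        len(phenology),
    )


def relative_climate_matrix(
    phenology: PhenologySeries, climate: ClimateSeries, n_lags: int = 365
) -> np.ndarray:
    """Years × lags matrix of temps `lag` days before each year's event.

    Lag 1 is the day before the event (the event day itself is excluded:
    a cue must precede the event)."""
    lags = np.arange(1, n_lags + 1)
    values = np.empty((len(phenology), n_lags))
    for i, (year, day) in enumerate(zip(phenology.years, phenology.event_day)):
        anchor = event_day_to_date(int(year), int(day))
        dates = [anchor - dt.timedelta(days=int(lag)) for lag in lags]
        values[i] = climate.temp_on(dates)
    return values


def search_relative(
    phenology: PhenologySeries,
    climate: ClimateSeries,
    statistics=STATISTICS,
    max_duration: int = 365,
) -> WindowSearchResult:
    """Exhaustive relative-frame (event-anchored) window search."""
    if len(phenology) < 4:
        raise ValidationError("need at least 4 years for a window search")
    values = relative_climate_matrix(phenology, climate)
    y = phenology.event_day.astype(float)
    table, baseline = _search_matrix(
        y, values, np.arange(1, values.shape[1] + 1), statistics, max_duration
    )
    return WindowSearchResult(
        table,
        baseline,
        "relative",
        (int(phenology.years.min()), int(phenology.years.max())),
        (0, 0),
        len(phenology),
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def window_aggregate_series(matrix: ClimateMatrix, window: WindowSpec) -> np.ndarray:
    """Per-year aggregate of the matrix over a fixed absolute window."""
    sel = (matrix.lags >= window.close) & (matrix.lags <= window.open)
    if sel.sum() != window.duration:
        raise ValidationError(
            f"matrix lags do not cover window {window.open}..{window.close}"
        )
    block = matrix.values[:, sel]  # lag ascending = newest -> oldest
    oldest_first = block[:, ::-1]
    return np.array([aggregate(row, window.statistic) for row in oldest_first])


def predict_from_cue(
    model: CueModel, matrix: ClimateMatrix, level: float = 0.95,
    observed: PhenologySeries | None = None,
) -> list[rc.PredictionResult]:
    """Predict event days for the matrix's years from a fitted cue model.

    Only absolute-frame cues can predict: a relative window is anchored
    to the event itself, which has not happened yet at prediction time.
    """
    if model.window.frame != "absolute":
        raise ValidationError(
            "relative-frame cues cannot be used predictively: the window is "
            "anchored to the event, so locating it requires the event to "
            "have already occurred"
        )
    x = window_aggregate_series(matrix, model.window)
    yhat = rc.predict(model.fit, x)
    lo, hi = rc.prediction_interval(model.fit, x, level)
    obs = {}
    if observed is not None:
        obs = dict(zip(observed.years.tolist(), observed.event_day.tolist()))
    return [
        rc.PredictionResult(
            int(year), float(p), float(l), float(h), obs.get(int(year))
        )
        for year, p, l, h in zip(matrix.years, yhat, lo, hi)
    ]
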