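"""Three-parameter growing degree-day (thermal-time) model.

From a start day-of-year t0, every degree of daily mean temperature
above a base temperature Tb accumulates; the event is predicted on the
first day the running sum reaches the requirement F*.  The three
parameters are estimated inside a bounded box (t0 in [1, 200], Tb in
[1, 10] °C, F* in [50, 1000] °C·days) by a seeded simulated-annealing
global search minimizing a sum-of-squares objective, and parameter
uncertainty comes from bootstrap resampling of years with percentile
confidence intervals.

Two objective modes are provided: ``direct`` (default) minimizes
Σ(predicted − observed)², while ``regression`` minimizes the residual
sum of squares of a linear model of predicted on observed dates, which
tolerates scale/offset bias in exchange for matching the literal
model-calibration description in parts of the thermal-time literature.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
from scipy.optimize import dual_annealing

from .io_model import ClimateSeries, PhenologySeries, ValidationError
from .regression_core import PredictionResult

#: Sentinel: the requirement was never reached within the year.
NOT_REACHED = -1

DEFAULT_BOUNDS = {
    "start_day": (1.0, 200.0),
    "base_temp": (1.0, 10.0),
    "requirement": (50.0, 1000.0),
}


@dataclass(frozen=True)
class GDDParams:
    """(t0, Tb, F*): start day-of-year, base temperature °C, requirement °C·days."""

    start_day: int
    base_temp: float
    requirement: float

    def as_array(self) -> np.ndarray:
        return np.array([self.start_day, self.base_temp, self.requirement], float)


@dataclass
class GDDFit:
    params: GDDParams
    objective: float
    objective_mode: str
    n_years: int
    boot_params: np.ndarray | None = None  # (reps, 3)
    ci_low: GDDParams | None = None
    ci_high: GDDParams | None = None


def gdd_event_date(daily_temps, params: GDDParams) -> int:
    """Predicted event day-of-year for one year of daily temperatures.

    ``daily_temps`` is indexed by day of year (element 0 = 1 January).
    Returns the smallest day e >= t0 with Σ_{d=t0..e} max(0, T_d − Tb)
    >= F*, or :data:`NOT_REACHED`.
    """
    temps = np.asarray(daily_temps, dtype=float)
    t0 = int(params.start_day)
    if t0 < 1 or t0 > len(temps):
        raise ValidationError(f"start day {t0} outside temperature coverage")
    tail = temps[t0 - 1 :]
    # trailing NaNs just mark the end of the year (day 366 in non-leap
    # years); a gap before the end of coverage is an error
    nan_pos = np.flatnonzero(np.isnan(tail))
    if len(nan_pos):
        if not np.isnan(tail[nan_pos[0] :]).all():
            raise ValidationError(
                f"temperature missing from day-of-year {t0 + int(nan_pos[0])}"
            )
        tail = tail[: nan_pos[0]]
    acc = np.cumsum(np.maximum(tail - params.base_temp, 0.0))
    hit = np.flatnonzero(acc >= params.requirement)
    if len(hit) == 0:
        return NOT_REACHED
    return t0 + int(hit[0])


def _predict_doy_matrix(temp_matrix: np.ndarray, t0: int, tb: float, f: float) -> np.ndarray:
    """Vectorized event day-of-year per row; NOT_REACHED where unattained."""
    tail = temp_matrix[:, t0 - 1 :]
    inc = np.maximum(np.nan_to_num(tail, nan=0.0) - tb, 0.0)
    inc[np.isnan(tail)] = 0.0
    acc = np.cumsum(inc, axis=1)
    reached = acc >= f
    any_hit = reached.any(axis=1)
    first = np.argmax(reached, axis=1)
    out = np.where(any_hit, t0 + first, NOT_REACHED)
    return out


class _GDDData:
    """Cached per-year day-of-year temperature layout for fast objectives."""

    def __init__(self, phenology: PhenologySeries, climate: ClimateSeries):
        self.years = phenology.years.copy()
        self.observed = phenology.event_day.astype(float)
        self.temp_matrix = climate.year_day_matrix(self.years)
        self.year_lengths = np.array(
            [366 if _is_leap(int(y)) else 365 for y in self.years]
        )
        # days since 1 April = doy − (doy of 31 March)
        self.april1_offset = np.array(
            [91 if _is_leap(int(y)) else 90 for y in self.years]
        )

    def predict_event_days(self, params: GDDParams) -> np.ndarray:
        """Predicted event dates in days since 1 April; years never
        reaching the requirement are pinned to 31 December."""
        doy = _predict_doy_matrix(
            self.temp_matrix,
            int(round(params.start_day)),
            params.base_temp,
            params.requirement,
        )
        doy = np.where(doy == NOT_REACHED, self.year_lengths, doy)
        return doy - self.april1_offset

    def subset(self, idx) -> "_GDDData":
        out = object.__new__(_GDDData)
        out.years = self.years[idx]
        out.observed = self.observed[idx]
        out.temp_matrix = self.temp_matrix[idx]
        out.year_lengths = self.year_lengths[idx]
        out.april1_offset = self.april1_offset[idx]
        return out


def _is_leap(y: int) -> bool:
    return y % 4 == 0 and (y % 100 != 0 or y % 400 == 0)


def _objective(data: _GDDData, mode: str):
    obs = data.observed
    obs_c = obs - obs.mean()
    sxx = float((obs_c**2).sum())

    def fun(v):
        params = GDDParams(int(round(v[0])), float(v[1]), float(v[2]))
        pred = data.predict_event_days(params)
        if mode == "direct":
            return float(((pred - obs) ** 2).sum())
        # 'regression': residual SS of predicted ~ observed
        if sxx == 0:
            return float(((pred - pred.mean()) ** 2).sum())
        slope = float((obs_c * (pred - pred.mean())).sum()) / sxx
        resid = (pred - pred.mean()) - slope * obs_c
        return float((resid**2).sum())

    return fun


def _check_bounds(bounds):
    for name, (lo, hi) in bounds.items():
        if lo >= hi:
            raise ValidationError(f"inverted bounds for {name}: ({lo}, {hi})")


def _grid_candidates(fun, box, per_axis=(12, 8, 24), top: int = 6):
    """Coarse box scan returning diverse low-objective starting points.

    The objective surface is a plateaued ridge (predictions are whole
    days) with a strong Tb–F* trade-off, so several well-separated
    starts are kept rather than the single best."""
    axes = [np.linspace(lo, hi, n) for (lo, hi), n in zip(box, per_axis)]
    pts, vals = [], []
    for a in axes[0]:
        for b in axes[1]:
            for c in axes[2]:
                pts.append((a, b, c))
                vals.append(fun((a, b, c)))
    order = np.argsort(vals)
    span = np.array([hi - lo for lo, hi in box])
    picked = []
    for idx in order:
        x = np.asarray(pts[idx])
        if all(np.max(np.abs(x - p) / span) > 0.08 for p in picked):
            picked.append(x)
        if len(picked) == top:
            break
    return picked


# pattern-search moves: single coordinates plus the Tb/F* and t0/F*
# trade-off diagonals of the ridge
_MOVES = np.array(
    [
        [1, 0, 0], [-1, 0, 0],
        [0, 1, 0], [0, -1, 0],
        [0, 0, 1], [0, 0, -1],
        [0, 1, 1], [0, -1, -1],
        [0, 1, -1], [0, -1, 1],
        [1, 0, -1], [-1, 0, 1],
    ],
    dtype=float,
)


def _pattern_polish(fun, x, box, steps=(16.0, 1.6, 64.0)):
    """Shrinking-step pattern search: gradient-free polish for a
    piecewise-constant objective, where annealing's local phase sees
    zero derivatives everywhere."""
    x = np.array(x, dtype=float)
    fx = fun(x)
    steps = np.array(steps, dtype=float)
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    while np.any(steps > np.array([0.5, 0.01, 0.25])):
        improved = False
        for move in _MOVES:
            cand = np.clip(x + move * steps, lo, hi)
            fc = fun(cand)
            if fc < fx:
                x, fx = cand, fc
                improved = True
        if not improved:
            steps *= 0.5
    return x, fx


def _fit_data(
    data: _GDDData, bounds, objective_mode: str, seed: int, maxiter: int,
    starts: int = 6, per_axis=(12, 8, 24),
) -> tuple[GDDParams, float]:
    box = [bounds["start_day"], bounds["base_temp"], bounds["requirement"]]
    fun = _objective(data, objective_mode)
    best_x, best_f = None, np.inf
    for start in _grid_candidates(fun, box, per_axis, starts):
        x, fx = _pattern_polish(fun, start, box)
        if fx < best_f:
            best_x, best_f = x, fx
    res = dual_annealing(
        fun,
        bounds=box,
        x0=best_x,
        seed=int(seed),
        maxiter=int(maxiter),
        no_local_search=True,
    )
    if res.fun < best_f:
        x, fx = _pattern_polish(fun, res.x, box)
        if fx < best_f:
            best_x, best_f = x, fx
    params = GDDParams(int(round(best_x[0])), float(best_x[1]), float(best_x[2]))
    return params, float(best_f)


def fit_gdd(
    phenology: PhenologySeries,
    climate: ClimateSeries,
    bounds: dict | None = None,
    objective_mode: str = "direct",
    seed: int = 0,
    maxiter: int = 250,
) -> GDDFit:
    """Fit the three parameters by seeded simulated annealing.

    Deterministic for a fixed (data, bounds, objective_mode, seed,
    maxiter).  Years in which the requirement is never reached predict
    31 December, giving a large but finite squared error everywhere in
    the box.
    """
    if len(phenology) < 5:
        raise ValidationError("need at least 5 years to fit a degree-day model")
    if objective_mode not in ("direct", "regression"):
        raise ValueError(f"objective_mode must be direct|regression, got {objective_mode!r}")
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    _check_bounds(bounds)
    data = _GDDData(phenology, climate)
    params, obj = _fit_data(data, bounds, objective_mode, seed, maxiter)
    return GDDFit(params, obj, objective_mode, len(phenology))


def bootstrap_gdd(
    fit: GDDFit,
    phenology: PhenologySeries,
    climate: ClimateSeries,
    reps: int = 1000,
    seed: int = 0,
    bounds: dict | None = None,
    maxiter: int = 60,
) -> GDDFit:
    """Percentile bootstrap CIs: resample years with replacement, refit.

    Each replicate refit runs the same seeded annealing search with its
    own sub-seed.  Returns the fit with ``boot_params`` and the per-
    parameter 2.5/97.5 percentile bounds attached.
    """
    if reps < 2:
        raise ValidationError(f"bootstrap needs reps >= 2, got {reps}")
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    _check_bounds(bounds)
    data = _GDDData(phenology, climate)
    rng = np.random.default_rng(seed)
    n = len(phenology)
    boot = np.empty((reps, 3))
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        # slightly lighter search per replicate; too coarse a replicate
        # budget biases the percentile CIs away from the thorough point fit
        params, _ = _fit_data(
            data.subset(idx), bounds, fit.objective_mode, sub_seed, maxiter,
            starts=4, per_axis=(10, 7, 20),
        )
        boot[r] = params.as_array()
    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    fit.boot_params = boot
    fit.ci_low = GDDParams(int(round(lo[0])), float(lo[1]), float(lo[2]))
    fit.ci_high = GDDParams(int(round(hi[0])), float(hi[1]), float(hi[2]))
    return fit


def predict_gdd(
    fit: GDDFit,
    phenology_years,
    climate: ClimateSeries,
    observed: PhenologySeries | None = None,
) -> list[PredictionResult]:
    """Point predictions from the fitted parameters; intervals from the
    envelope of predictions over all 2³ corners of the per-parameter
    bootstrap confidence bounds (a conservative superset of pairing the
    lower bounds together and the upper bounds together).
    """
    years = np.asarray(list(phenology_years), dtype=int)
    dummy = PhenologySeries(years, np.ones(len(years), dtype=int), (1, 1))
    data = _GDDData(dummy, climate)
    point = data.predict_event_days(fit.params).astype(float)
    if fit.ci_low is None or fit.ci_high is None:
        lo = hi = point
    else:
        corners = []
        for t0 in (fit.ci_low.start_day, fit.ci_high.start_day):
            for tb in (fit.ci_low.base_temp, fit.ci_high.base_temp):
                for f in (fit.ci_low.requirement, fit.ci_high.requirement):
                    corners.append(
                        data.predict_event_days(GDDParams(t0, tb, f)).astype(float)
                    )
        corners = np.stack(corners)
        lo = np.minimum(corners.min(axis=0), point)
        hi = np.maximum(corners.max(axis=0), point)
    obs = {}
    if observed is not None:
        obs = dict(zip(observed.years.tolist(), observed.event_day.tolist()))
    return [
        PredictionResult(int(y), float(p), float(l), float(h), obs.get(int(y)))
        for y, p, l, h in zip(years, point, lo, hi)
    ]
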