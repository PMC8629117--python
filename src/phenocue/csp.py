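"""Climate sensitivity profile (CSP).

The event date is regressed on a single day's mean temperature, one
regression per lag day back from the reference day.  The resulting
per-lag slope and R² profiles are smoothed with a penalized regression
spline (smoothing parameter by GCV), and the critical window is the
longest run of consecutive lag days on which the smoothed coefficient
falls in its extreme 2.5% tail *and* the smoothed R² exceeds its 97.5%
quantile.  A mean-temperature cue over that window is then fitted with
an ordinary linear model.

Because temperature usually advances phenology, the coefficient tail is
sign-aware by default: when the median smoothed coefficient is negative
the lower 2.5% tail is used, otherwise the upper tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import regression_core as rc
from ._pspline import bspline_design, difference_penalty, penalized_lstsq
from .io_model import ClimateMatrix, PhenologySeries, ValidationError
from .sliding_window import CueModel, WindowSpec, window_aggregate_series


class EmptyWindowError(ValidationError):
    """No lag day passed both profile thresholds."""


@dataclass
class CSPProfile:
    """Raw and smoothed sensitivity profiles with the extracted window."""

    lags: np.ndarray
    coef: np.ndarray
    r2: np.ndarray
    coef_smooth: np.ndarray
    r2_smooth: np.ndarray
    coef_threshold: float
    r2_threshold: float
    coef_tail: str                  # 'lower' or 'upper' (resolved)
    critical: WindowSpec


def daily_regressions(
    phenology: PhenologySeries, matrix: ClimateMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-lag OLS of event day on that single day's temperature.

    Returns (coef, r2) arrays, one entry per matrix lag.  A lag with
    constant temperature across years is degenerate: recorded as
    (0, 0) with a warning.
    """
    if len(phenology) < 4:
        raise ValidationError("need at least 4 years for daily regressions")
    if not np.array_equal(phenology.years, matrix.years):
        matrix = matrix.select_years(phenology.years)
    fits = rc.fit_linear_many(matrix.values, phenology.event_day.astype(float))
    degenerate = fits["sxx"] <= 0
    if degenerate.any():
        warnings.warn(
            f"constant temperature at lag(s) {matrix.lags[degenerate].tolist()}; "
            "coefficient and R² recorded as 0",
            stacklevel=2,
        )
    return fits["slope"], fits["r2"]


def smooth_profile(
    values, lags=None, basis_dim: int = 50, penalty_order: int = 2, lambdas=None
) -> np.ndarray:
    """Penalized cubic-spline smooth of a per-lag profile (GCV penalty)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValidationError("need at least 10 lags to smooth a profile")
    if lags is None:
        lags = np.arange(len(values))
    if basis_dim >= len(values):
        raise ValidationError(
            f"basis_dim ({basis_dim}) must be smaller than the number of lags "
            f"({len(values)})"
        )
    B = bspline_design(np.asarray(lags, dtype=float), basis_dim)
    P = difference_penalty(basis_dim, penalty_order)
    fit = penalized_lstsq(B, values, P, lambdas)
    return B @ fit.coef


def extract_critical_window(
    lags,
    coef_smooth,
    r2_smooth,
    coef_tail: str = "auto",
    coef_q: float = 0.025,
    r2_q: float = 0.975,
) -> tuple[WindowSpec, float, float, str]:
    """Quantile-threshold extraction of the critical window.

    A lag day qualifies when its smoothed coefficient is at or beyond
    the ``coef_q`` empirical quantile (lower tail for negative effects,
    upper for positive) and its smoothed R² is at or above the ``r2_q``
    quantile.  The longest run of consecutive qualifying lags is the
    window; ties break toward the run nearer the reference day.
    """
    lags = np.asarray(lags)
    coef_smooth = np.asarray(coef_smooth, dtype=float)
    r2_smooth = np.asarray(r2_smooth, dtype=float)
    if np.ptp(coef_smooth) < 1e-12 or np.ptp(r2_smooth) < 1e-12:
        raise EmptyWindowError(
            "flat sensitivity profile: quantile thresholds cannot single out "
            "a sensitive period"
        )
    if coef_tail == "auto":
        # tail of the dominant effect; the median is uninformative when
        # most lags are insensitive (it sits at ~0 either way)
        extreme = coef_smooth[np.argmax(np.abs(coef_smooth))]
        coef_tail = "lower" if extreme <= 0 else "upper"
    if coef_tail == "lower":
        coef_threshold = float(np.quantile(coef_smooth, coef_q))
        pass_coef = coef_smooth <= coef_threshold
    elif coef_tail == "upper":
        coef_threshold = float(np.quantile(coef_smooth, 1.0 - coef_q))
        pass_coef = coef_smooth >= coef_threshold
    else:
        raise ValueError(f"coef_tail must be auto|lower|upper, got {coef_tail!r}")
    r2_threshold = float(np.quantile(r2_smooth, r2_q))
    passing = pass_coef & (r2_smooth >= r2_threshold)
    if not passing.any():
        raise EmptyWindowError(
            "no lag day passes both profile thresholds; relax coef_q/r2_q "
            "or inspect the smoothed profiles"
        )
    # longest consecutive run of passing lag positions
    runs = []
    start = None
    for i, p in enumerate(passing):
        if p and start is None:
            start = i
        elif not p and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(passing) - 1))
    # length descending; among equals the run with the smaller close lag wins
    best = max(runs, key=lambda r: (r[1] - r[0], -lags[r[0]]))
    window = WindowSpec(
        open=int(lags[best[1]]), close=int(lags[best[0]]),
        frame="absolute", statistic="mean",
    )
    return window, coef_threshold, r2_threshold, coef_tail


def compute_profile(
    phenology: PhenologySeries,
    matrix: ClimateMatrix,
    basis_dim: int = 50,
    coef_tail: str = "auto",
    coef_q: float = 0.025,
    r2_q: float = 0.975,
) -> CSPProfile:
    """Full CSP pipeline: daily regressions → smoothing → window extraction."""
    coef, r2 = daily_regressions(phenology, matrix)
    coef_s = smooth_profile(coef, matrix.lags, basis_dim)
    r2_s = smooth_profile(r2, matrix.lags, basis_dim)
    window, coef_thr, r2_thr, tail = extract_critical_window(
        matrix.lags, coef_s, r2_s, coef_tail, coef_q, r2_q
    )
    return CSPProfile(
        lags=matrix.lags,
        coef=coef,
        r2=r2,
        coef_smooth=coef_s,
        r2_smooth=r2_s,
        coef_threshold=coef_thr,
        r2_threshold=r2_thr,
        coef_tail=tail,
        critical=window,
    )


def fit_csp_cue(
    phenology: PhenologySeries, matrix: ClimateMatrix, window: WindowSpec
) -> CueModel:
    """Linear cue model: event day on mean temperature over the window."""
    if not np.array_equal(phenology.years, matrix.years):
        matrix = matrix.select_years(phenology.years)
    window = WindowSpec(window.open, window.close, "absolute", "mean")
    x = window_aggregate_series(matrix, window)
    fit = rc.fit_linear(x, phenology.event_day.astype(float))
    return CueModel(
        window,
        fit,
        (int(phenology.years.min()), int(phenology.years.max())),
        matrix.reference_day,
    )


def run_csp(
    phenology: PhenologySeries,
    matrix: ClimateMatrix,
    basis_dim: int = 50,
    coef_tail: str = "auto",
) -> tuple[CSPProfile, CueModel]:
    """Profile extraction followed by the cue-model fit."""
    profile = compute_profile(phenology, matrix, basis_dim, coef_tail)
    model = fit_csp_cue(phenology, matrix, profile.critical)
    return profile, model
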