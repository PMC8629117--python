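"""Simple-linear-regression machinery shared by the window-based methods.

Everything here is ordinary least squares with one predictor.  It is
written in closed form (rather than delegating to a model-fitting
library) because the exhaustive window search evaluates hundreds of
thousands of candidate regressions and needs them fully vectorized;
:func:`fit_linear_many` scores an arbitrary matrix of candidate
predictors in one pass.  Model comparison uses AICc with the Gaussian
maximum-likelihood log-likelihood, and prediction intervals use the
classical normal-theory t-interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LinearFit",
    "PredictionResult",
    "fit_linear",
    "fit_linear_many",
    "intercept_only_rss",
    "gaussian_aicc",
    "aicc",
    "aicc_intercept_only",
    "predict",
    "prediction_interval",
    "K_SLOPE_MODEL",
    "K_INTERCEPT_ONLY",
]

#: Parameter counts for AICc: coefficients plus the residual variance.
K_INTERCEPT_ONLY = 2
K_SLOPE_MODEL = 3


@dataclass(frozen=True)
class LinearFit:
    """A fitted simple linear regression y = intercept + slope * x."""

    intercept: float
    slope: float
    slope_se: float
    r2: float          # multiple R²
    r2_adj: float      # adjusted R²
    n: int
    sigma2: float      # residual variance, RSS / (n - 2)
    x_mean: float
    sxx: float
    rss: float

    @property
    def df_resid(self) -> int:
        return self.n - 2


@dataclass(frozen=True)
class PredictionResult:
    """A point prediction with its prediction interval (days since 1 April)."""

    year: int
    predicted: float
    pi_low: float
    pi_high: float
    observed: float | None = None

    @property
    def pi_width(self) -> float:
        return self.pi_high - self.pi_low

    def covers(self, value: float) -> bool:
        return self.pi_low <= value <= self.pi_high


def _check_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, got {len(x)}")
    return x, y


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares of y on a single predictor x."""
    x, y = _check_xy(x, y)
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("degenerate predictor: var(x) = 0")
    sxy = float(((x - xm) * (y - ym)).sum())
    syy = float(((y - ym) ** 2).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    rss = syy - slope * sxy
    rss = max(rss, 0.0)
    sigma2 = rss / (n - 2)
    slope_se = math.sqrt(sigma2 / sxx)
    r2 = 0.0 if syy == 0.0 else 1.0 - rss / syy
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return LinearFit(intercept, slope, slope_se, r2, r2_adj, n, sigma2, xm, sxx, rss)


def fit_linear_many(X, y) -> dict:
    """Vectorized OLS of y on each column of X.

    Parameters
    ----------
    X : (n, m) array — m candidate predictors.
    y : (n,) array — shared response.

    Returns
    -------
    dict of (m,) arrays: slope, intercept, slope_se, r2, r2_adj, rss,
    sigma2, sxx, x_mean, aicc (slope-model AICc).  Columns with zero
    variance get slope 0, r2 0 and aicc = +inf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X rows must match len(y)")
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    sxx = (Xc**2).sum(axis=0)
    sxy = Xc.T @ yc
    syy = float((yc**2).sum())
    ok = sxx > 0
    slope = np.zeros(X.shape[1])
    np.divide(sxy, sxx, out=slope, where=ok)
    intercept = ym - slope * xm
    rss = np.maximum(syy - slope * sxy, 0.0)
    rss[~ok] = syy
    sigma2 = rss / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope_se = np.sqrt(np.where(ok, sigma2 / np.where(ok, sxx, 1.0), np.nan))
    r2 = np.zeros_like(slope) if syy == 0 else 1.0 - rss / syy
    r2 = np.where(ok, r2, 0.0)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    aicc_vals = gaussian_aicc(rss, n, K_SLOPE_MODEL)
    aicc_vals = np.where(ok, aicc_vals, np.inf)
    return {
        "slope": slope,
        "intercept": intercept,
        "slope_se": slope_se,
        "r2": r2,
        "r2_adj": r2_adj,
        "rss": rss,
        "sigma2": sigma2,
        "sxx": sxx,
        "x_mean": xm,
        "aicc": aicc_vals,
    }


def intercept_only_rss(y) -> float:
    y = np.asarray(y, dtype=float)
    return float(((y - y.mean()) ** 2).sum())


def gaussian_aicc(rss, n: int, k: int):
    """AICc from a residual sum of squares under the Gaussian ML likelihood.

    k counts estimated parameters including the residual variance
    (intercept-only model: k=2; slope model: k=3).  The maximized
    log-likelihood is -n/2 * (log(2π σ̂²_ML) + 1) with σ̂²_ML = RSS/n.
    """
    if n - k - 1 <= 0:
        raise ValueError(
            f"AICc undefined: n - k - 1 = {n - k - 1} <= 0 (n={n}, k={k})"
        )
    rss = np.asarray(rss, dtype=float)
    with np.errstate(divide="ignore"):
        loglik = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
    out = -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
    return out if out.ndim else float(out)


def aicc(fit: LinearFit) -> float:
    """AICc of a fitted slope model (k = 3)."""
    return gaussian_aicc(fit.rss, fit.n, K_SLOPE_MODEL)


def aicc_intercept_only(y) -> float:
    """AICc of the intercept-only baseline model (k = 2)."""
    y = np.asarray(y, dtype=float)
    return gaussian_aicc(intercept_only_rss(y), len(y), K_INTERCEPT_ONLY)


def predict(fit: LinearFit, x_new) -> np.ndarray:
    return fit.intercept + fit.slope * np.asarray(x_new, dtype=float)


def prediction_interval(fit: LinearFit, x_new, level: float = 0.95):
    """Normal-theory prediction interval for a new observation at x_new.

    ŷ ± t_{n-2, (1+level)/2} · s · sqrt(1 + 1/n + (x_new - x̄)² / Sxx)
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    x_new = np.asarray(x_new, dtype=float)
    yhat = predict(fit, x_new)
    tq = stats.t.ppf(0.5 * (1.0 + level), fit.df_resid)
    s = math.sqrt(fit.sigma2)
    half = tq * s * np.sqrt(1.0 + 1.0 / fit.n + (x_new - fit.x_mean) ** 2 / fit.sxx)
    return yhat - half, yhat + half
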