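"""Penalized B-spline signal regression (PSR).

The annual event date is regressed on the whole 365-day temperature
history at once: y_i = α + Σ_d β(d)·x_i(d) + ε_i, with the coefficient
function β expanded in a cubic B-spline basis over lag days and a
first-order difference penalty on the basis coefficients to keep
adjacent days' partial coefficients close.  The penalty weight λ is
chosen by generalized cross-validation over a log-spaced grid.

"Important" days are those whose partial coefficient differs from zero
by more than twice its pointwise standard error, computed from the
penalized least-squares covariance σ̂²·M⁻¹ Z'Z M⁻¹ (M the penalized,
Z'Z the unpenalized Gram matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import regression_core as rc
from ._pspline import DEFAULT_LAMBDA_GRID, bspline_design, difference_penalty, penalized_lstsq
from .io_model import ClimateMatrix, PhenologySeries, ValidationError


@dataclass
class PSRModel:
    """A fitted signal regression with its coefficient function."""

    intercept: float
    knots: int               # number of B-spline basis functions
    degree: int
    penalty_order: int
    lam: float
    lags: np.ndarray
    beta: np.ndarray         # partial coefficient per lag (days per °C per day)
    beta_se: np.ndarray      # pointwise SE per lag
    fitted: np.ndarray
    r2: float
    r2_adj: float
    sigma2: float
    edf: float
    n: int
    gcv: np.ndarray = field(repr=False)
    lambda_grid: np.ndarray = field(repr=False)
    # internals needed for prediction
    _coef: np.ndarray = field(repr=False, default=None)
    _cov: np.ndarray = field(repr=False, default=None)
    _basis: np.ndarray = field(repr=False, default=None)

    @property
    def df_resid(self) -> float:
        return self.n - self.edf


def fit_psr(
    phenology: PhenologySeries,
    matrix: ClimateMatrix,
    knots: int = 20,
    degree: int = 3,
    penalty_order: int = 1,
    lambdas=None,
) -> PSRModel:
    """Fit the penalized signal regression.

    ``knots`` is the number of basis functions; it cannot exceed one
    less than the sample size (here enforced as knots <= n - 2 so the
    intercept stays estimable).
    """
    if not np.array_equal(phenology.years, matrix.years):
        matrix = matrix.select_years(phenology.years)
    n = len(phenology)
    if n < 5:
        raise ValidationError(f"need at least 5 years to fit a PSR, got {n}")
    if knots > n - 2:
        raise ValidationError(
            f"number of basis knots ({knots}) cannot exceed one less than the "
            f"sample size; with an intercept this requires knots <= n - 2 = {n - 2}"
        )
    y = phenology.event_day.astype(float)
    X = matrix.values
    B = bspline_design(matrix.lags.astype(float), knots, degree)
    Z = np.column_stack([np.ones(n), X @ B])
    P = np.zeros((knots + 1, knots + 1))
    P[1:, 1:] = difference_penalty(knots, penalty_order)
    pfit = penalized_lstsq(Z, y, P, lambdas)
    theta = pfit.coef[1:]
    beta = B @ theta
    cov = pfit.sigma2 * pfit.cov_unscaled
    beta_cov = B @ cov[1:, 1:] @ B.T
    beta_se = np.sqrt(np.maximum(np.diag(beta_cov), 0.0))
    fitted = Z @ pfit.coef
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - pfit.rss / tss if tss > 0 else 0.0
    denom = max(n - pfit.edf, 1.0)
    r2_adj = 1.0 - (pfit.rss / denom) / (tss / (n - 1)) if tss > 0 else 0.0
    return PSRModel(
        intercept=float(pfit.coef[0]),
        knots=knots,
        degree=degree,
        penalty_order=penalty_order,
        lam=pfit.lam,
        lags=matrix.lags.copy(),
        beta=beta,
        beta_se=beta_se,
        fitted=fitted,
        r2=r2,
        r2_adj=r2_adj,
        sigma2=pfit.sigma2,
        edf=pfit.edf,
        n=n,
        gcv=pfit.gcv,
        lambda_grid=np.asarray(pfit.lambda_grid, dtype=float),
        _coef=pfit.coef,
        _cov=cov,
        _basis=B,
    )


def important_days(model: PSRModel) -> np.ndarray:
    """Lags whose partial coefficient exceeds twice its standard error."""
    return model.lags[np.abs(model.beta) > 2.0 * model.beta_se]


def important_window(model: PSRModel):
    """(open, close) = extremal important lags, or None when none qualify."""
    days = important_days(model)
    if len(days) == 0:
        return None
    return int(days.max()), int(days.min())


def predict_psr(
    model: PSRModel,
    matrix: ClimateMatrix,
    level: float = 0.95,
    observed: PhenologySeries | None = None,
) -> list[rc.PredictionResult]:
    """Predict event days from full temperature histories.

    ŷ = α + Σ_d β(d)·x_new(d); the prediction interval is
    ŷ ± t_df · sqrt(se_fit² + σ̂²) with df = n − edf.
    """
    if not np.array_equal(matrix.lags, model.lags):
        raise ValidationError("test matrix lag layout differs from training")
    Z_new = np.column_stack([np.ones(len(matrix.years)), matrix.values @ model._basis])
    yhat = Z_new @ model._coef
    se_fit2 = np.einsum("ij,jk,ik->i", Z_new, model._cov, Z_new)
    df = max(1.0, model.df_resid)
    tq = stats.t.ppf(0.5 * (1.0 + level), df)
    half = tq * np.sqrt(np.maximum(se_fit2, 0.0) + model.sigma2)
    obs = {}
    if observed is not None:
        obs = dict(zip(observed.years.tolist(), observed.event_day.tolist()))
    return [
        rc.PredictionResult(int(yr), float(p), float(p - h), float(p + h),
                            obs.get(int(yr)))
        for yr, p, h in zip(matrix.years, yhat, half)
    ]
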