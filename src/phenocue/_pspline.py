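"""Penalized B-spline (P-spline) building blocks.

Equally spaced cubic B-spline bases with a difference penalty on the
basis coefficients, ridge-type solution of the penalized least-squares
system, and smoothing-parameter choice by generalized cross-validation
(GCV) over a log-spaced grid.  Shared by the profile smoother and the
signal-regression model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import solve

DEFAULT_LAMBDA_GRID = np.logspace(-4, 6, 41)


def bspline_design(x, n_basis: int, degree: int = 3) -> np.ndarray:
    """Design matrix of ``n_basis`` equally spaced B-splines evaluated at x.

    Knots extend ``degree`` segments beyond [min(x), max(x)] in the usual
    P-spline fashion, so the basis sums to one everywhere on the range.
    """
    x = np.asarray(x, dtype=float)
    if n_basis <= degree:
        raise ValueError(f"n_basis must exceed the degree ({degree})")
    lo, hi = float(x.min()), float(x.max())
    nseg = n_basis - degree
    h = (hi - lo) / nseg
    knots = lo + h * np.arange(-degree, nseg + degree + 1)
    B = BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()
    assert B.shape == (len(x), n_basis)
    return B


def difference_penalty(n_basis: int, order: int) -> np.ndarray:
    """Penalty matrix D'D for the ``order``-th difference of coefficients."""
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


@dataclass
class PenalizedFit:
    """Solution of min ||y - Z c||² + λ c' P c at the GCV-chosen λ."""

    coef: np.ndarray
    lam: float
    edf: float
    rss: float
    gcv: np.ndarray          # GCV score per grid point
    lambda_grid: np.ndarray
    cov_unscaled: np.ndarray  # M⁻¹ Z'Z M⁻¹ (multiply by σ̂² for covariance)
    sigma2: float             # RSS / (n - edf)


def penalized_lstsq(
    Z: np.ndarray,
    y: np.ndarray,
    P: np.ndarray,
    lambdas=None,
) -> PenalizedFit:
    """Penalized least squares with GCV choice of λ.

    GCV(λ) = n·RSS(λ) / (n − edf(λ))², edf = tr(hat matrix).
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambdas is None:
        lambdas = DEFAULT_LAMBDA_GRID
    lambdas = np.asarray(lambdas, dtype=float)
    n = len(y)
    G = Z.T @ Z
    Zty = Z.T @ y
    yty = float(y @ y)
    gcv = np.empty(len(lambdas))
    results = []
    for i, lam in enumerate(lambdas):
        M = G + lam * P
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular penalized system at lambda={lam}") from exc
        coef = Minv @ Zty
        edf = float(np.trace(Minv @ G))
        rss = max(yty - 2.0 * coef @ Zty + coef @ G @ coef, 0.0)
        denom = max(n - edf, 1e-8)
        gcv[i] = n * rss / denom**2
        results.append((coef, edf, rss, Minv))
    k = int(np.argmin(gcv))
    coef, edf, rss, Minv = results[k]
    cov_unscaled = Minv @ G @ Minv
    sigma2 = rss / max(n - edf, 1.0)
    return PenalizedFit(
        coef=coef,
        lam=float(lambdas[k]),
        edf=edf,
        rss=rss,
        gcv=gcv,
        lambda_grid=lambdas,
        cov_unscaled=cov_unscaled,
        sigma2=sigma2,
    )
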