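"""Predictive evaluation of cue-identification methods.

Three experiment designs are supported, mirroring the questions a
phenologist asks of a cue model:

* ``near_future`` — nested training spans (shrunk in 10-year increments
  from either end of the full range), each predicting the 5 years
  directly after its end: how does data volume affect accuracy?
* ``fixed_test`` — the same training spans all predicting one held-out
  terminal test block: how does temporal distance to the test years
  matter, separately from data volume?
* ``kfold`` — the full span partitioned into 5-year folds, each
  predicted from the complementary years: overall accuracy/precision.

For every (method, split) the cue is re-identified from scratch on the
training years only, then used to predict the test years.  Metrics:
mean absolute error (MAE), mean signed error (predicted − observed),
mean 95% prediction-interval width, interval coverage, and the
least-squares trend of per-fold mean signed error against fold mid-year
(a diagnostic for a drifting cue–phenology relationship).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import csp as csp_mod
from . import gdd as gdd_mod
from . import psr as psr_mod
from . import regression_core as rc
from . import sliding_window as sw
from .io_model import (
    DEFAULT_REFERENCE_DAY,
    ClimateSeries,
    PhenologySeries,
    ValidationError,
    build_climate_matrix,
)

REGRESSION_METHODS = ("swa", "csp", "psr")


@dataclass(frozen=True)
class Split:
    train_years: tuple[int, ...]
    test_years: tuple[int, ...]

    @property
    def label(self) -> str:
        return f"{self.test_years[0]}-{self.test_years[-1]}"

    @property
    def test_mid_year(self) -> float:
        return float(np.mean(self.test_years))


@dataclass(frozen=True)
class SplitPlan:
    mode: str
    splits: tuple[Split, ...]


def make_training_sets(
    full: tuple[int, int],
    increment: int = 10,
    test_width: int = 5,
    mode: str = "near_future",
) -> SplitPlan:
    """Build the training/test splits for one experiment design.

    For ``near_future``/``fixed_test`` the training spans are the full
    range plus the range shrunk in ``increment``-year steps from the
    start and from the end (down to a single increment).  For ``kfold``
    the full range is partitioned into ``test_width``-year folds and
    each fold is predicted from all remaining years.
    """
    start, end = int(full[0]), int(full[1])
    length = end - start + 1
    if mode in ("near_future", "fixed_test"):
        if length < 2 * increment:
            raise ValidationError(
                f"range of {length} years is too short for increment {increment}"
            )
        if length % increment != 0:
            raise ValidationError(
                f"increment {increment} does not divide the {length}-year range"
            )
        trainings = [(start, end)]
        trainings += [
            (start + k * increment, end) for k in range(1, length // increment)
        ]
        trainings += [
            (start, end - k * increment) for k in range(1, length // increment)
        ]
        splits = []
        for lo, hi in trainings:
            t_end = hi if mode == "near_future" else end
            test = tuple(range(t_end + 1, t_end + 1 + test_width))
            splits.append(Split(tuple(range(lo, hi + 1)), test))
        return SplitPlan(mode, tuple(splits))
    if mode == "kfold":
        if length % test_width != 0:
            raise ValidationError(
                f"fold width {test_width} does not divide the {length}-year range"
            )
        all_years = list(range(start, end + 1))
        splits = []
        for i in range(length // test_width):
            test = tuple(all_years[i * test_width : (i + 1) * test_width])
            train = tuple(y for y in all_years if y not in test)
            splits.append(Split(train, test))
        return SplitPlan(mode, tuple(splits))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _aligned(predictions, observations):
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or len(p) == 0:
        raise ValueError("predictions and observations must be equal-length, non-empty")
    return p, o


def mae(predictions, observations) -> float:
    """Mean absolute error in days."""
    p, o = _aligned(predictions, observations)
    return float(np.abs(p - o).mean())


def mean_signed_error(predictions, observations) -> float:
    """Mean of (predicted − observed); negative = predictions too early."""
    p, o = _aligned(predictions, observations)
    return float((p - o).mean())


def coverage(pi_low, pi_high, observations) -> float:
    """Fraction of observations inside their closed prediction interval."""
    lo = np.asarray(pi_low, dtype=float)
    hi = np.asarray(pi_high, dtype=float)
    o = np.asarray(observations, dtype=float)
    return float(((lo <= o) & (o <= hi)).mean())


def error_trend(errors, mid_years) -> tuple[float, float]:
    """OLS of per-fold mean signed error on fold mid-year.

    Returns (slope in days/year, multiple R²)."""
    errors = np.asarray(errors, dtype=float)
    if len(errors) < 3:
        raise ValidationError("need at least 3 folds for an error trend")
    fit = rc.fit_linear(np.asarray(mid_years, dtype=float), errors)
    return fit.slope, fit.r2


# ---------------------------------------------------------------------------
# method adapters
# ---------------------------------------------------------------------------

class SWAMethod:
    """Absolute sliding-window cue, refit per training set."""

    name = "swa"

    def __init__(self, statistics=sw.STATISTICS, max_duration: int = 365,
                 reference_day=DEFAULT_REFERENCE_DAY):
        self.statistics = statistics
        self.max_duration = max_duration
        self.reference_day = reference_day

    def fit_predict(self, train: PhenologySeries, test: PhenologySeries,
                    climate: ClimateSeries, seed: int):
        m_train = build_climate_matrix(climate, train.years, self.reference_day)
        result = sw.search_absolute(train, m_train, self.statistics, self.max_duration)
        model = result.best_model()
        m_test = build_climate_matrix(climate, test.years, self.reference_day)
        return sw.predict_from_cue(model, m_test, observed=test)


class CSPMethod:
    """Climate-sensitivity-profile cue (profiles exclude the reference day)."""

    name = "csp"

    def __init__(self, basis_dim: int = 50, coef_tail: str = "auto",
                 reference_day=DEFAULT_REFERENCE_DAY):
        self.basis_dim = basis_dim
        self.coef_tail = coef_tail
        self.reference_day = reference_day

    def fit_predict(self, train, test, climate, seed):
        m_train = build_climate_matrix(
            climate, train.years, self.reference_day, include_reference_day=False
        )
        _, model = csp_mod.run_csp(train, m_train, self.basis_dim, self.coef_tail)
        m_test = build_climate_matrix(
            climate, test.years, self.reference_day, include_reference_day=False
        )
        return sw.predict_from_cue(model, m_test, observed=test)


class PSRMethod:
    """Penalized signal regression on the full lag history."""

    name = "psr"

    def __init__(self, knots: int = 20, reference_day=DEFAULT_REFERENCE_DAY):
        self.knots = knots
        self.reference_day = reference_day

    def fit_predict(self, train, test, climate, seed):
        m_train = build_climate_matrix(climate, train.years, self.reference_day)
        model = psr_mod.fit_psr(train, m_train, knots=self.knots)
        m_test = build_climate_matrix(climate, test.years, self.reference_day)
        return psr_mod.predict_psr(model, m_test, observed=test)


class GDDMethod:
    """Degree-day model; intervals from bootstrap CI corner predictions."""

    name = "gdd"

    def __init__(self, bootstrap_reps: int = 50, objective_mode: str = "direct",
                 maxiter: int = 250, boot_maxiter: int = 40, bounds: dict | None = None):
        self.bootstrap_reps = bootstrap_reps
        self.objective_mode = objective_mode
        self.maxiter = maxiter
        self.boot_maxiter = boot_maxiter
        self.bounds = bounds

    def fit_predict(self, train, test, climate, seed):
        fit = gdd_mod.fit_gdd(
            train, climate, bounds=self.bounds,
            objective_mode=self.objective_mode, seed=seed, maxiter=self.maxiter,
        )
        if self.bootstrap_reps >= 2:
            gdd_mod.bootstrap_gdd(
                fit, train, climate, reps=self.bootstrap_reps, seed=seed + 1,
                bounds=self.bounds, maxiter=self.boot_maxiter,
            )
        return gdd_mod.predict_gdd(fit, test.years, climate, observed=test)


METHOD_REGISTRY = {
    "swa": SWAMethod,
    "csp": CSPMethod,
    "psr": PSRMethod,
    "gdd": GDDMethod,
}


def _resolve_methods(methods):
    out = []
    for m in methods:
        if isinstance(m, str):
            name = m.lower()
            if name == "swr":
                warnings.warn(
                    "the relative sliding window is excluded from prediction "
                    "experiments: its cue is defined by the timing of the event "
                    "itself, so identifying it requires the event to have "
                    "already occurred",
                    stacklevel=3,
                )
                continue
            if name not in METHOD_REGISTRY:
                raise ValueError(f"unknown method {m!r}")
            out.append(METHOD_REGISTRY[name]())
        else:
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-(method, split) metrics and the underlying predictions."""

    mode: str
    metrics: pd.DataFrame      # method, train span, test span, mae, ...
    predictions: pd.DataFrame  # method, year, predicted, pi_low, pi_high, observed

    def summary(self) -> pd.DataFrame:
        """Per-method aggregates: mean MAE, mean PI width, overall coverage."""
        rows = []
        for name, grp in self.predictions.groupby("method", sort=False):
            rows.append(
                {
                    "method": name,
                    "mae": mae(grp["predicted"], grp["observed"]),
                    "mean_signed_error": mean_signed_error(
                        grp["predicted"], grp["observed"]
                    ),
                    "pi_width": float(
                        (grp["pi_high"] - grp["pi_low"]).mean()
                    ),
                    "coverage": coverage(
                        grp["pi_low"], grp["pi_high"], grp["observed"]
                    ),
                }
            )
        return pd.DataFrame(rows)

    def error_trend(self, methods=None) -> tuple[float, float]:
        """Trend of per-(method, fold) mean signed error vs fold mid-year.

        ``methods`` restricts the pooled points (e.g. the regression-based
        subset); default uses every method in the report."""
        df = self.metrics
        if methods is not None:
            df = df[df["method"].isin(methods)]
        return error_trend(
            df["mean_signed_error"].to_numpy(), df["test_mid_year"].to_numpy()
        )


def run_experiment(
    phenology: PhenologySeries,
    climate: ClimateSeries,
    methods,
    plan: SplitPlan,
    seed: int = 0,
) -> EvaluationReport:
    """Re-identify each method's cue per split and score its predictions."""
    methods = _resolve_methods(methods)
    have = set(phenology.years.tolist())
    metric_rows, pred_rows = [], []
    for si, split in enumerate(plan.splits):
        need = set(split.train_years) | set(split.test_years)
        if not need <= have:
            raise ValidationError(
                f"phenology does not cover years {sorted(need - have)}"
            )
        train = phenology.select(split.train_years)
        test = phenology.select(split.test_years)
        for method in methods:
            name_tag = sum(ord(c) for c in method.name)  # stable across runs
            fold_seed = (int(seed) * 100003 + si * 131 + name_tag) % (2**31 - 1)
            preds = method.fit_predict(train, test, climate, fold_seed)
            p = np.array([pr.predicted for pr in preds])
            lo = np.array([pr.pi_low for pr in preds])
            hi = np.array([pr.pi_high for pr in preds])
            o = np.array([pr.observed for pr in preds], dtype=float)
            metric_rows.append(
                {
                    "method": method.name,
                    "train_start": split.train_years[0],
                    "train_end": split.train_years[-1],
                    "n_train": len(split.train_years),
                    "test_start": split.test_years[0],
                    "test_end": split.test_years[-1],
                    "test_mid_year": split.test_mid_year,
                    "mae": mae(p, o),
                    "mean_signed_error": mean_signed_error(p, o),
                    "pi_width": float((hi - lo).mean()),
                    "coverage": coverage(lo, hi, o),
                }
            )
            for pr in preds:
                pred_rows.append(
                    {
                        "method": method.name,
                        "test_start": split.test_years[0],
                        "year": pr.year,
                        "predicted": pr.predicted,
                        "pi_low": pr.pi_low,
                        "pi_high": pr.pi_high,
                        "observed": pr.observed,
                    }
                )
    return EvaluationReport(
        plan.mode, pd.DataFrame(metric_rows), pd.DataFrame(pred_rows)
    )
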