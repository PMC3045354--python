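"""Whole-set companion metrics and the per-model evaluation record.

MAE and Kendall tau-b summarize a model's accuracy and rank ordering over
the entire set; the SALI quantities (SCI, S(0), S(1)) from
:mod:`salicurves.core` localize the rank-order assessment across the
activity-cliff landscape. `evaluate_model` bundles all five into one record,
the row format used for model-comparison tables.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .core import sali_curve
from .errors import DegenerateInputError, ValidationError
from .similarity import SimilarityMatrix

STATISTICS = ("mae", "kendall_tau", "sci", "s0", "s1")


@dataclass
class ModelEvaluation:
    """One model scored on one compound set."""

    model: str
    label: str
    n: int
    mae: float
    kendall_tau: float
    sci: float
    s0: float
    s1: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def mae(observed, predicted) -> float:
    """Mean absolute error of predictions."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValidationError("observed and predicted lengths differ")
    if observed.size == 0:
        raise DegenerateInputError("MAE undefined on empty input")
    return float(np.mean(np.abs(observed - predicted)))


def kendall_tau(observed, predicted) -> float:
    """Tie-adjusted (tau-b) Kendall rank correlation."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValidationError("observed and predicted lengths differ")
    if observed.size < 2:
        raise DegenerateInputError("Kendall tau needs at least 2 observations")
    if np.ptp(observed) == 0 or np.ptp(predicted) == 0:
        raise DegenerateInputError("Kendall tau undefined for a constant vector")
    tau = stats.kendalltau(observed, predicted, variant="b").statistic
    return float(tau)


def evaluate_model(
    observed,
    predicted,
    sim: SimilarityMatrix,
    model: str = "model",
    label: str = "",
    method: str = "exact",
    step: float = 0.01,
    reference_max: float | None = None,
) -> ModelEvaluation:
    """MAE, Kendall tau-b, SCI, S(0) and S(1) for one model on one set."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    curve = sali_curve(
        observed, predicted, sim, method=method, step=step, reference_max=reference_max
    )
    return ModelEvaluation(
        model=model,
        label=label,
        n=int(observed.size),
        mae=mae(observed, predicted),
        kendall_tau=kendall_tau(observed, predicted),
        sci=curve.sci,
        s0=curve.s0,
        s1=curve.s1,
    )


def s0_tau_regression(evals: list[ModelEvaluation]) -> RegressionResult:
    """Ordinary least squares of S(0) on Kendall tau across evaluations.

    On tie-free landscapes S(0) is itself a Kendall coefficient restricted to
    the eligible pairs, so the fitted slope is expected to sit near 1.
    """
    if len(evals) < 3:
        raise DegenerateInputError("regression needs at least 3 evaluations")
    taus = np.array([e.kendall_tau for e in evals])
    s0s = np.array([e.s0 for e in evals])
    if np.ptp(taus) == 0:
        raise DegenerateInputError("regression undefined: all tau values identical")
    fit = stats.linregress(taus, s0s)
    return RegressionResult(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))
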