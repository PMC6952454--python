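"""Zero-training transfer: spatial filter for a new subject from one trial.

Given a fitted group model for A subjects, the filter for a new subject is
obtained in closed form by maximizing the covariance between the new
subject's component and the subject-mean component of the group, under a
unit-variance constraint on the new component:

    w_new ∝ Q_new^{-1} X_new^(1) Σ_α U_α^T w_α

The coefficient matrices ``X_new^(1) U_α^T`` weigh each existing filter by
how much the new trial resembles subject α's trial mean, so the new filter
is a similarity-weighted combination of the group's filters.  The Lagrange
multiplier of the constraint is never computed: the unnormalized filter is
rescaled post hoc so the new component has unit (population) variance.

Condition prediction projects an unlabeled trial through each condition's
predictive filter and picks the condition whose group-mean component
correlates best with the projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .datasets import _as_float_matrix
from .group import GtrcaModel, SubjectSummaries
from .trca import regularize_spd

__all__ = ["PredictionResult", "predictive_filter", "predict_condition"]


@dataclass
class PredictionResult:
    """Outcome of zero-training condition prediction for one trial."""

    predicted_condition: int
    correlations: np.ndarray  # Pearson r per condition, same order as the models
    w_new: np.ndarray  # predictive filter of the winning condition


def predictive_filter(
    model: GtrcaModel,
    summaries: list[SubjectSummaries] | None,
    X_new_trial: np.ndarray,
    Q_new: np.ndarray,
    X_new_continuous: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form filter for a new subject from a single trial.

    ``summaries`` may be omitted; the group model retains its subjects' trial
    means, and only ``Σ_α U_α^T w_α = Σ_α y_α`` enters the formula.  The
    filter is scaled so the new subject's component has unit population
    variance over ``X_new_continuous`` (the single trial stands in when no
    continuous data exists).
    """
    X1 = _as_float_matrix(X_new_trial, "X_new_trial")
    if X1.shape[1] != len(model.group_mean_trc):
        raise ValueError(
            f"trial length {X1.shape[1]} does not match the model's tau "
            f"{len(model.group_mean_trc)}"
        )
    if summaries is not None:
        target = np.sum([s.U.T @ w for s, w in zip(summaries, model.filters)], axis=0)
    else:
        target = np.sum(model.mean_trcs, axis=0)
    Qr = regularize_spd(np.asarray(Q_new, dtype=np.float64))
    w = linalg.solve(Qr, X1 @ target, assume_a="pos")
    ref = X1 if X_new_continuous is None else _as_float_matrix(X_new_continuous)
    y = w @ ref
    sd = y.std()  # population
    if sd == 0:
        raise ValueError("new subject's component is constant; cannot normalize its variance")
    return w / sd


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise ValueError("constant time series has no correlation")
    return float(a @ b / denom)


def predict_condition(
    models: list[GtrcaModel],
    X_new_trial: np.ndarray,
    Q_new: np.ndarray,
    condition_ids: list[int] | None = None,
) -> PredictionResult:
    """Predict the stimulation condition of one unlabeled trial.

    For each candidate condition, builds the predictive filter from that
    condition's group model, projects the trial, and correlates the result
    with the condition's group-mean component; the argmax wins.  Invariant
    to positive rescaling of the trial and to each model's global sign.
    """
    if len(models) == 0:
        raise ValueError("need at least one condition model")
    if condition_ids is None:
        condition_ids = list(range(len(models)))
    rs = np.empty(len(models))
    filters = []
    for i, m in enumerate(models):
        w = predictive_filter(m, None, X_new_trial, Q_new)
        y = w @ _as_float_matrix(X_new_trial, "X_new_trial")
        rs[i] = _pearson(y, m.group_mean_trc)
        filters.append(w)
    best = int(np.argmax(rs))
    return PredictionResult(
        predicted_condition=int(condition_ids[best]),
        correlations=rs,
        w_new=filters[best],
    )
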