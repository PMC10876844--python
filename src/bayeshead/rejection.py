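"""Selective classification: reject predictions above an uncertainty threshold.

A prediction is accepted when its Monte-Carlo uncertainty (the predicted
class's standard deviation over stochastic passes) is at most a user-set
threshold t; rejected cases are meant for expert review. Performance
metrics are then computed on the retained subset only, and sweeping t
produces the accuracy/AUC/fraction-retained trade-off curve: small t keeps
only confident cases (fewer, more accurate), large t retains everything and
recovers the unrejected baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .bayesify import MCPrediction
from .errors import EmptySubsetError

__all__ = [
    "DEFAULT_THRESHOLDS",
    "RejectionResult",
    "Metrics",
    "ThresholdCurve",
    "apply_threshold",
    "compute_metrics",
    "threshold_curve",
]

# Default sweep grid for the uncertainty threshold t.
DEFAULT_THRESHOLDS = (0.002, 0.005, 0.01, 0.02, 0.05, 0.10, 0.15, 0.2)


@dataclass
class RejectionResult:
    threshold: float
    accepted: np.ndarray  # boolean per sample
    fraction_retained: float


@dataclass
class Metrics:
    """Classification metrics with class 1 (disease) as positive.

    ``auc`` is None when the evaluated subset contains a single class and
    the ROC is undefined.
    """

    accuracy: float
    f1: float
    precision: float
    recall: float
    auc: Optional[float]
    n_evaluated: int


@dataclass
class ThresholdCurve:
    """Rows of (threshold, accuracy, auc, fraction retained), sorted by t.

    Rows whose retained subset was empty carry NaN metrics; single-class
    subsets carry NaN AUC only.
    """

    frame: pd.DataFrame

    def row(self, t: float) -> pd.Series:
        return self.frame.loc[np.isclose(self.frame["threshold"], t)].iloc[0]


def apply_threshold(uncertainties: Sequence[float], t: float) -> RejectionResult:
    """Accept samples with uncertainty <= t (equality accepted)."""
    if t < 0:
        raise ValueError("threshold t must be non-negative")
    u = np.asarray(uncertainties, dtype=float)
    accepted = u <= t
    return RejectionResult(
        threshold=float(t),
        accepted=accepted,
        fraction_retained=float(accepted.mean()) if len(u) else 0.0,
    )


def compute_metrics(predicted, scores, truth) -> Metrics:
    """Accuracy/precision/recall/F1 and rank-based AUC (ties averaged).

    ``scores`` are the positive-class (label 1) mean probabilities used for
    the ROC. Empty inputs raise :class:`EmptySubsetError` so threshold
    sweeps can flag rather than fail.
    """
    predicted = np.asarray(predicted)
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if not (len(predicted) == len(scores) == len(truth)):
        raise ValueError("predicted, scores and truth must have equal length")
    if len(truth) == 0:
        raise EmptySubsetError("no samples to evaluate")
    auc = None
    if len(np.unique(truth)) == 2:
        auc = float(roc_auc_score(truth, scores))
    return Metrics(
        accuracy=float(accuracy_score(truth, predicted)),
        f1=float(f1_score(truth, predicted, pos_label=1, zero_division=0)),
        precision=float(precision_score(truth, predicted, pos_label=1, zero_division=0)),
        recall=float(recall_score(truth, predicted, pos_label=1, zero_division=0)),
        auc=auc,
        n_evaluated=len(truth),
    )


def threshold_curve(
    mcpreds: Sequence[MCPrediction],
    truth,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> ThresholdCurve:
    """Sweep the rejection threshold and evaluate the retained subset at each t."""
    if len(thresholds) == 0:
        raise ValueError("threshold grid must be non-empty")
    truth = np.asarray(truth)
    uncert = np.array([p.uncertainty for p in mcpreds])
    predicted = np.array([p.predicted_class for p in mcpreds])
    scores = np.array([p.mean_probs[1] for p in mcpreds])

    rows = []
    for t in sorted(float(t) for t in thresholds):
        res = apply_threshold(uncert, t)
        keep = res.accepted
        try:
            m = compute_metrics(predicted[keep], scores[keep], truth[keep])
            rows.append(
                {
                    "threshold": t,
                    "accuracy": m.accuracy,
                    "auc": np.nan if m.auc is None else m.auc,
                    "fraction": res.fraction_retained,
                    "n_evaluated": m.n_evaluated,
                }
            )
        except EmptySubsetError:
            rows.append(
                {
                    "threshold": t,
                    "accuracy": np.nan,
                    "auc": np.nan,
                    "fraction": 0.0,
                    "n_evaluated": 0,
                }
            )
    return ThresholdCurve(frame=pd.DataFrame(rows))
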