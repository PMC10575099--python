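"""Regression deviation metrics and micro/macro multi-class metrics.

MAE, RMSE and MAPE (reported as a fraction, not a percentage) score the
stress estimators; precision/recall/F1 with micro and macro averaging plus
accuracy score the discrete health-level classification.  Micro metrics pool
true/false positives over labels — for single-label multi-class input,
micro-precision, micro-recall and micro-F1 all equal accuracy; macro metrics
are unweighted means over labels, with empty predicted classes contributing
0 to the mean (logged convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, UndefinedStatisticError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionReport:
    mae: float
    mape: float | None
    rmse: float
    factor: str = ""
    horizon_min: float = float("nan")


def regression_metrics(truth, pred, factor: str = "",
                       horizon_min: float = float("nan")) -> RegressionReport:
    """MAE, MAPE (fraction) and RMSE of a prediction against truth.

    MAPE requires every truth value nonzero and raises otherwise.
    """
    t = np.asarray(truth, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape or t.size == 0:
        raise ConfigurationError("truth and pred must be equal-length nonempty series")
    err = p - t
    if np.any(t == 0.0):
        raise UndefinedStatisticError("MAPE undefined: truth contains zeros")
    return RegressionReport(
        mae=float(np.mean(np.abs(err))),
        mape=float(np.mean(np.abs(err / t))),
        rmse=float(np.sqrt(np.mean(err**2))),
        factor=factor,
        horizon_min=horizon_min,
    )


@dataclass
class ConfusionMatrix:
    """Counts[i, j] = samples with true label i predicted as label j."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ConfigurationError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ConfigurationError("confusion-matrix counts must be nonnegative")

    @classmethod
    def from_labels(cls, truth, pred, labels=None) -> "ConfusionMatrix":
        truth, pred = list(truth), list(pred)
        if len(truth) != len(pred) or not truth:
            raise ConfigurationError("truth and pred must be equal-length nonempty")
        if labels is None:
            labels = tuple(dict.fromkeys(list(truth) + list(pred)))
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for a, b in zip(truth, pred):
            counts[index[a], index[b]] += 1
        return cls(labels=tuple(labels), counts=counts)


def classification_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy plus precision/recall/F1 under micro and macro averaging."""
    counts = cm.counts
    total = int(counts.sum())
    if total < 1:
        raise ConfigurationError("confusion matrix must contain at least one sample")
    tp = np.diag(counts).astype(float)
    pred_pos = counts.sum(axis=0).astype(float)
    true_pos = counts.sum(axis=1).astype(float)
    fp = pred_pos - tp
    fn = true_pos - tp

    def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
        out = np.zeros_like(num)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        for i in np.flatnonzero(~ok):
            logger.warning("label %r has no %s; contributes 0 to macro mean",
                           cm.labels[i], what)
        return out

    precision = _safe_div(tp, pred_pos, "predicted positives")
    recall = _safe_div(tp, true_pos, "true positives")
    pr_sum = precision + recall
    f1 = np.divide(2 * precision * recall, pr_sum,
                   out=np.zeros_like(pr_sum), where=pr_sum > 0)

    per_label = {
        lab: {"precision": float(precision[i]), "recall": float(recall[i]), "f1": float(f1[i])}
        for i, lab in enumerate(cm.labels)
    }

    micro_p = tp.sum() / (tp.sum() + fp.sum())
    micro_r = tp.sum() / (tp.sum() + fn.sum())
    micro_f1 = 2 * micro_p * micro_r / (micro_p + micro_r) if micro_p + micro_r else 0.0
    return {
        "accuracy": float(tp.sum() / total),
        "precision_micro": float(micro_p),
        "recall_micro": float(micro_r),
        "f1_micro": float(micro_f1),
        "precision_macro": float(precision.mean()),
        "recall_macro": float(recall.mean()),
        "f1_macro": float(f1.mean()),
        "per_label": per_label,
    }
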