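"""Binary-classification evaluation: confusion matrix, rate metrics, ROC/AUC,
error histogram, and regression diagnostics.

The four rate metrics (leukemia = positive class):

* accuracy    = (TP + TN) / (TP + TN + FP + FN) x 100
* precision   = TP / (TP + FP) x 100
* sensitivity = TP / (TP + FN) x 100
* specificity = TN / (TN + FP) x 100

AUC is the standard rank (Mann-Whitney) statistic — the probability a random
positive outscores a random negative, ties counted one half — reported as a
percentage.  A ratio with a zero denominator is reported as NaN with a
warning, never silently as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix2x2",
    "EvaluationReport",
    "confusion",
    "metrics",
    "roc_auc",
    "error_histogram",
    "regression_r",
    "evaluate_scores",
]

logger = logging.getLogger(__name__)

POSITIVE_LABEL = 1  # leukemia


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts with leukemia as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class EvaluationReport:
    """Full diagnostic bundle for one evaluated split."""

    confusion: ConfusionMatrix2x2
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: np.ndarray          # (n, 2) of (FPR, TPR)
    error_bin_edges: np.ndarray
    error_bin_counts: np.ndarray
    regression_r: float
    extras: dict = field(default_factory=dict)


def _as_binary(y, name: str) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "UO":  # label strings
        arr = (arr == "leukemia").astype(np.int64)
    else:
        arr = arr.astype(np.int64)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1 or normal/leukemia labels)")
    return arr


def confusion(y_true, y_pred) -> ConfusionMatrix2x2:
    """Tally TP/FN/FP/TN with leukemia (1) as positive."""
    t = _as_binary(y_true, "y_true")
    p = _as_binary(y_pred, "y_pred")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("confusion of empty input is undefined")
    return ConfusionMatrix2x2(
        tp=int(np.sum((t == 1) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined: zero denominator", name)
        return float("nan")
    return 100.0 * num / den


def metrics(cm: ConfusionMatrix2x2) -> dict:
    """Accuracy, precision, sensitivity and specificity as percentages."""
    if cm.total == 0:
        raise ValueError("metrics of an all-zero confusion matrix are undefined")
    return {
        "accuracy": _ratio(cm.tp + cm.tn, cm.total, "accuracy"),
        "precision": _ratio(cm.tp, cm.tp + cm.fp, "precision"),
        "sensitivity": _ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp, "specificity"),
    }


def roc_auc(scores, y_true) -> tuple[float, np.ndarray]:
    """Rank-statistic AUC (percentage) and the ROC curve points.

    AUC = P(score of a random positive > score of a random negative), ties
    counted 1/2 — equivalently the normalized Mann-Whitney U statistic.
    Curve points are (FPR, TPR) over all score thresholds, from (0, 0) to
    (1, 1).
    """
    s = np.asarray(scores, dtype=np.float64)
    t = _as_binary(y_true, "y_true")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes in y_true")
    ranks = rankdata(s)
    u = ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2.0
    auc = 100.0 * u / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(t, s)
    points = np.column_stack([fpr, tpr])
    return float(auc), points


def error_histogram(actual, predicted, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of prediction errors (actual - predicted) in equal-width bins."""
    a = np.asarray(actual, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {p.shape}")
    if a.size == 0:
        raise ValueError("error_histogram of empty input is undefined")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    errors = a - p
    counts, edges = np.histogram(errors, bins=bins)
    return edges, counts


def regression_r(actual, predicted) -> float:
    """Pearson correlation between actual and predicted values."""
    a = np.asarray(actual, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if a.shape != p.shape or a.size < 2:
        raise ValueError("regression_r needs two equal-length vectors of size >= 2")
    if a.std() == 0 or p.std() == 0:
        logger.warning("regression_r undefined: zero variance input")
        return float("nan")
    return float(np.corrcoef(a, p)[0, 1])


def evaluate_scores(y_true, y_pred, scores, histogram_bins: int = 20) -> EvaluationReport:
    """Assemble the full report from labels, predictions and positive scores."""
    cm = confusion(y_true, y_pred)
    m = metrics(cm)
    auc, points = roc_auc(scores, y_true)
    t = _as_binary(y_true, "y_true").astype(np.float64)
    s = np.asarray(scores, dtype=np.float64)
    # Error histogram compares targets with probability-like scores; signed
    # margin scores are squashed through a logistic first.
    prob_like = s if (s.min() >= 0.0 and s.max() <= 1.0) else 1.0 / (1.0 + np.exp(-s))
    edges, counts = error_histogram(t, prob_like, bins=histogram_bins)
    return EvaluationReport(
        confusion=cm,
        accuracy=m["accuracy"],
        precision=m["precision"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        auc=auc,
        roc_points=points,
        error_bin_edges=edges,
        error_bin_counts=counts,
        regression_r=regression_r(t, prob_like) if np.std(prob_like) > 0 else float("nan"),
    )
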