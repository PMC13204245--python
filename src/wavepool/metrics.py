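"""Confusion-matrix metrics, ROC AUC and probability-calibration measures.

The positive class is *malignant* (label 1).  Zero-denominator conventions:
precision := 0 when no positive predictions exist, F1 := 0 when
precision + recall = 0.  Report tables round percentages half-even to two
decimals.

Calibration: the Brier score is the mean squared difference between the
positive-class probability and the binary label; ECE partitions the
positive-class probability into ten equal-width bins and averages the
absolute accuracy-confidence gap weighted by bin occupancy (empty bins are
skipped).  With equal-width bins none straddles 0.5, so this equals the
predicted-class-confidence formulation on binary problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    n: int
    auc: Optional[float] = None
    brier: Optional[float] = None
    ece: Optional[float] = None
    reliability: Optional[List[Tuple[float, float, int]]] = None

    def as_percent_row(self) -> dict:
        """Percentages rounded half-even to 2 decimals, for report tables."""
        def pct(v):
            return None if v is None else round(100 * v, 2)
        return {
            "accuracy": pct(self.accuracy), "precision": pct(self.precision),
            "recall": pct(self.recall), "specificity": pct(self.specificity),
            "f1": pct(self.f1), "auc": pct(self.auc), "n": self.n,
        }


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionMatrix:
    """Binary confusion matrix with malignant (1) as the positive class."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have the same shape")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall (sensitivity), specificity and F1."""
    accuracy = (cm.tp + cm.tn) / cm.total
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp > 0 else 0.0
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else 0.0
    specificity = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall,
                         specificity=specificity, f1=f1, n=cm.total)


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Empirical ROC AUC; equals the Mann-Whitney statistic with half ties."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


def brier(labels: np.ndarray, positive_probs: np.ndarray) -> float:
    """Mean squared difference between positive probability and label."""
    y = np.asarray(labels, dtype=np.float64)
    p = np.asarray(positive_probs, dtype=np.float64)
    return float(np.mean((p - y) ** 2))


def _bin_index(p: np.ndarray, bins: int) -> np.ndarray:
    idx = np.minimum((p * bins).astype(int), bins - 1)
    return idx


def reliability_curve(labels: np.ndarray, positive_probs: np.ndarray,
                      bins: int = 10) -> List[Tuple[float, float, int]]:
    """Per-bin (mean confidence, empirical accuracy, count); empty bins skipped.

    Confidence/accuracy are expressed for the positive class: mean predicted
    positive probability vs. empirical positive fraction within the bin.
    """
    y = np.asarray(labels, dtype=np.float64)
    p = np.asarray(positive_probs, dtype=np.float64)
    idx = _bin_index(p, bins)
    out = []
    for b in range(bins):
        sel = idx == b
        nb = int(sel.sum())
        if nb == 0:
            continue
        out.append((float(p[sel].mean()), float(y[sel].mean()), nb))
    return out


def ece(labels: np.ndarray, positive_probs: np.ndarray, bins: int = 10) -> float:
    """Expected calibration error over equal-width probability bins."""
    n = len(np.asarray(labels))
    curve = reliability_curve(labels, positive_probs, bins)
    return float(sum(nb / n * abs(acc - conf) for conf, acc, nb in curve))


def full_report(labels: np.ndarray, positive_probs: np.ndarray,
                threshold: float = 0.5, bins: int = 10) -> MetricsReport:
    """Threshold the probabilities and compute the complete metric report."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(positive_probs, dtype=np.float64)
    preds = (p >= threshold).astype(int)
    report = classification_metrics(confusion(y, preds))
    report.auc = roc_auc(y, p) if len(np.unique(y)) == 2 else None
    report.brier = brier(y, p)
    report.ece = ece(y, p, bins)
    report.reliability = reliability_curve(y, p, bins)
    return report


def fit_recalibrator(method: str, val_scores: np.ndarray,
                     val_labels: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Fit a monotone score -> probability mapping on held-out data.

    ``platt`` fits a one-dimensional logistic regression on the scores;
    ``isotonic`` fits a non-decreasing step function.  Both require the
    validation set to contain both classes.
    """
    s = np.asarray(val_scores, dtype=np.float64).ravel()
    y = np.asarray(val_labels).astype(int).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("recalibration requires both classes in the validation set")
    if method == "platt":
        lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=10000)
        lr.fit(s[:, None], y)
        return lambda x: lr.predict_proba(np.asarray(x, dtype=np.float64).ravel()[:, None])[:, 1]
    if method == "isotonic":
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        iso.fit(s, y)
        return lambda x: iso.predict(np.asarray(x, dtype=np.float64).ravel())
    raise ValueError(f"method must be 'platt' or 'isotonic', got {method!r}")
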