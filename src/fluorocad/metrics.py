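"""Evaluation statistics: classification metrics, ROC/AUC, IOU/mIOU, and
paired t-tests for model comparisons.

AUC follows the Mann-Whitney U convention (ties count one half), which is
what a trapezoidal integral of the threshold-swept ROC yields; IOU is the
two-mask intersection-over-union with the both-empty case defined as 1.0
(needed for artifact frames where truth and prediction are both empty);
mIOU averages the target-class and background-class IOUs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

__all__ = ["ConfusionCounts", "classification_metrics", "roc_auc",
           "iou", "mean_iou", "paired_t_test", "DegenerateTestError"]


class DegenerateTestError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, predicted, truth):
        predicted = np.asarray(predicted, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        return cls(tp=int((predicted & truth).sum()),
                   fp=int((predicted & ~truth).sum()),
                   tn=int((~predicted & ~truth).sum()),
                   fn=int((~predicted & truth).sum()))


def classification_metrics(counts: ConfusionCounts) -> dict:
    """Sensitivity, specificity, precision, accuracy.

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never as 0.
    """
    def ratio(num, den):
        return num / den if den > 0 else None

    c = counts
    return {
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "precision": ratio(c.tp, c.tp + c.fp),
        "accuracy": ratio(c.tp + c.tn, c.total),
    }


def roc_auc(scores, labels):
    """ROC curve points and trapezoidal AUC over a sweep of the unique
    scores.  Returns ``(points, auc)`` with points as (fpr, tpr) pairs.
    Equals the tie-half-credit normalized Mann-Whitney U statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _roc_curve(labels.astype(int), scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks; 1.0 when both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)


def mean_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Two-class mean IOU: average of the target-class IOU and the
    background-class (complement) IOU."""
    return 0.5 * (iou(a, b) + iou(~np.asarray(a, bool), ~np.asarray(b, bool)))


def paired_t_test(x, y, tail: str = "two_tailed"):
    """Classical paired t-test with n-1 degrees of freedom.

    ``tail='one_tailed'`` tests the alternative mean(x) > mean(y) and
    reports half the two-tailed p on that side.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise DegenerateTestError("zero-variance differences: t undefined")
    if tail == "two_tailed":
        res = stats.ttest_rel(x, y)
    elif tail == "one_tailed":
        res = stats.ttest_rel(x, y, alternative="greater")
    else:
        raise ValueError("tail must be 'one_tailed' or 'two_tailed'")
    return float(res.statistic), float(res.pvalue)
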