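"""ROC analysis, Youden cut-off, confusion counts and OOB AUC.

Conventions: the positive class is coded 1 (affected, or PMC); higher
scores mean "more positive"; a sample is predicted positive when its
score is >= the threshold; AUC uses the Mann-Whitney rank statistic with
half credit for ties, which equals the trapezoidal area under the
empirical ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

__all__ = ["RocResult", "ConfusionCounts", "roc_auc", "youden_cutoff",
           "confusion_at_cutoff", "oob_auc"]


@dataclass
class RocResult:
    fpr: np.ndarray         # 1 - specificity, non-decreasing
    tpr: np.ndarray         # sensitivity, non-decreasing
    thresholds: np.ndarray  # score cut-offs for each point
    auc: float


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_correct(self) -> int:
        return self.tp + self.tn


def _validate(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and rank-statistic AUC (ties counted half)."""
    scores, labels = _validate(scores, labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = rankdata(scores)  # midranks handle ties
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, thr = roc_curve(labels, scores)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(auc))


def youden_cutoff(roc: RocResult) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity (lower false-positive rate,
    i.e. the higher threshold).
    """
    j = roc.tpr - roc.fpr
    best = np.flatnonzero(j == j.max())
    # roc_curve thresholds are decreasing; the earliest tied index has the
    # highest threshold and the lowest fpr
    idx = best[np.argmin(roc.fpr[best])]
    thr = roc.thresholds[idx]
    if np.isinf(thr):
        # the "predict nobody" corner: smallest float above the top score
        top = roc.thresholds[1] if len(roc.thresholds) > 1 else 0.0
        thr = np.nextafter(top, np.inf)
    return float(thr)


def confusion_at_cutoff(scores, labels, threshold: float) -> ConfusionCounts:
    """Counts with predicted positive = (score >= threshold)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if np.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)), fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)), fn=int(np.sum(~pred & pos)))


def oob_auc(votes, labels) -> float:
    """AUC of out-of-bag vote fractions for the positive class.

    ``votes`` may contain NaN for samples never out-of-bag; these are
    excluded with a warning reporting the count.
    """
    votes = np.asarray(votes, float)
    labels = np.asarray(labels, int)
    keep = np.isfinite(votes)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} sample(s) never out-of-bag; excluded from AUC")
    return roc_auc(votes[keep], labels[keep]).auc
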