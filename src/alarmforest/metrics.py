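"""Alarm-classification performance measures.

Covers the confusion-matrix cells, the penalized challenge score
100*(TP+TN)/(TP+FP+TN+5*FN) that punishes a missed true alarm five times
as harshly as a false one, the ROC curve with trapezoidal AUC, and
Youden-index (J = TPR + TNR - 1 + 1 = TPR + (1 - FPR)) optimal-cutoff
selection.

Thresholding convention: a score is classified YES iff it strictly exceeds
the threshold.  Candidate thresholds are the midpoints between consecutive
distinct scores plus one sentinel below the minimum and the maximum score
itself, so every achievable confusion table is represented exactly without
an arbitrary grid.  A fixed-grid mode is available for strict replication
of grid-based threshold sweeps.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import as_binary


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN cells with YES as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class CutoffResult:
    """A selected probability threshold and its Youden statistic J."""

    threshold: float
    j: float


def confusion(labels, predicted) -> ConfusionCounts:
    """Count confusion cells; both arguments accept YES/NO, bool or 0/1."""
    y = as_binary(labels)
    yhat = as_binary(predicted)
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions differ in length")
    return ConfusionCounts(
        tp=int((y & yhat).sum()),
        fp=int((~y & yhat).sum()),
        tn=int((~y & ~yhat).sum()),
        fn=int((y & ~yhat).sum()),
    )


def challenge_score(cc: ConfusionCounts) -> float:
    """Accuracy-like score with a fivefold false-negative penalty, in [0, 100]."""
    if cc.total == 0:
        raise ValueError("cannot score an empty confusion table")
    return 100.0 * (cc.tp + cc.tn) / (cc.tp + cc.fp + cc.tn + 5 * cc.fn)


def tpr_tnr(cc: ConfusionCounts) -> tuple[float, float]:
    """Sensitivity and specificity; an undefined marginal is returned as NaN."""
    tpr = cc.tp / (cc.tp + cc.fn) if (cc.tp + cc.fn) > 0 else math.nan
    tnr = cc.tn / (cc.tn + cc.fp) if (cc.tn + cc.fp) > 0 else math.nan
    return tpr, tnr


def _check_two_classes(y: np.ndarray) -> None:
    if y.all() or not y.any():
        raise ValueError("both classes must be present")


def candidate_thresholds(scores) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus sentinels.

    The low sentinel sits strictly below the minimum score (classifying
    everything YES under the strict-> rule); the high candidate is the
    maximum score itself (classifying everything NO).
    """
    uniq = np.unique(np.asarray(scores, dtype=float))
    spread = uniq[-1] - uniq[0]
    lo = uniq[0] - (spread / 2 if spread > 0 else 0.5)
    mids = (uniq[:-1] + uniq[1:]) / 2
    return np.concatenate(([lo], mids, [uniq[-1]]))


def _rates_at(scores: np.ndarray, y: np.ndarray, thresholds: np.ndarray):
    pos = scores[y]
    neg = scores[~y]
    tpr = (pos[None, :] > thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] > thresholds[:, None]).mean(axis=1)
    return tpr, fpr


def roc_curve(scores, labels, thresholds=None) -> pd.DataFrame:
    """Operating points (threshold, TPR, FPR) of the strict-> classifier.

    Includes the trivial endpoints (TPR, FPR) = (1, 1) and (0, 0).  Pass
    ``thresholds`` for a fixed replication grid instead of exact midpoints.
    """
    scores = np.asarray(scores, dtype=float)
    y = as_binary(labels)
    _check_two_classes(y)
    if thresholds is None:
        thresholds = candidate_thresholds(scores)
    else:
        thresholds = np.sort(np.asarray(thresholds, dtype=float))
    thresholds = np.concatenate(([-np.inf], thresholds, [np.inf]))
    tpr, fpr = _rates_at(scores, y, thresholds)
    return pd.DataFrame({"threshold": thresholds, "tpr": tpr, "fpr": fpr})


def auc(scores, labels) -> float:
    """Trapezoidal area under the ROC curve.

    With midpoint thresholds this equals the rank statistic P(score_pos >
    score_neg) with ties counted one half.
    """
    curve = roc_curve(scores, labels)
    # threshold ascending -> FPR descending; integrate in FPR order
    fpr = curve["fpr"].to_numpy()[::-1]
    tpr = curve["tpr"].to_numpy()[::-1]
    return float(np.trapezoid(tpr, fpr))


def youden_cutoff(scores, labels, thresholds=None) -> CutoffResult:
    """Threshold maximizing J = TPR + (1 - FPR) over the candidate set.

    Ties are broken toward the smallest maximizing threshold, which favors
    sensitivity — the direction the fivefold FN penalty of the challenge
    score rewards.  A threshold below the minimum score encodes the
    all-positive rule.
    """
    scores = np.asarray(scores, dtype=float)
    y = as_binary(labels)
    _check_two_classes(y)
    if thresholds is None:
        thresholds = candidate_thresholds(scores)
    else:
        thresholds = np.sort(np.asarray(thresholds, dtype=float))
    tpr, fpr = _rates_at(scores, y, thresholds)
    j = tpr + (1.0 - fpr)
    best = int(np.argmax(j))  # first occurrence = smallest threshold
    return CutoffResult(threshold=float(thresholds[best]), j=float(j[best]))
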