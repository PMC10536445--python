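"""Confusion-matrix metrics and ROC AUC for per-second apnea scoring.

Apnea seconds are the positive class. Accuracy, recall (sensitivity),
precision, specificity and F1 follow the usual confusion-matrix formulas;
zero-denominator cases are defined as 0 so that degenerate patients (e.g.
no apnea at all) still produce a report, and such reports are flagged via
``MetricsReport.degenerate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score


class UndefinedAUCError(ValueError):
    """ROC AUC is undefined when only one class is present."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    accuracy: float
    recall: float
    precision: float
    specificity: float
    f1: float
    auc: float | None = None
    degenerate: bool = False

    @property
    def sensitivity(self) -> float:
        return self.recall

    def to_dict(self) -> dict:
        d = {
            "auc": None if self.auc is None else float(self.auc),
            "accuracy": float(self.accuracy),
            "f1": float(self.f1),
            "sensitivity": float(self.recall),
            "specificity": float(self.specificity),
            "precision": float(self.precision),
        }
        if self.degenerate:
            d["degenerate"] = True
        return d


def confusion_from_scores(labels, scores, threshold: float = 0.5) -> ConfusionMatrix:
    """Tally a confusion matrix; a sample is predicted apnea when
    ``score >= threshold``."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionMatrix(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, recall, precision, specificity and F1 from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("cannot compute metrics from an empty confusion matrix")
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    degenerate = (cm.tp + cm.fn == 0) or (cm.tp + cm.fp == 0) or (cm.tn + cm.fp == 0)
    return MetricsReport(
        accuracy=(cm.tp + cm.tn) / cm.total,
        recall=recall,
        precision=precision,
        specificity=specificity,
        f1=f1,
        degenerate=degenerate,
    )


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve.

    Equals the probability that a random apnea second outscores a random
    normal second, ties counted one half.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def report_from_scores(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full per-second report: thresholded confusion metrics plus AUC."""
    rep = compute_metrics(confusion_from_scores(labels, scores, threshold))
    try:
        rep.auc = roc_auc(labels, scores)
    except UndefinedAUCError:
        rep.auc = None
        rep.degenerate = True
    return rep
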