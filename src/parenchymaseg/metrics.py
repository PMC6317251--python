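"""Classification metrics for the patch classifier.

The model-selection score is the average F-score

    F_avg = P_nlp*R_nlp/(P_nlp+R_nlp) + P_lp*R_lp/(P_lp+R_lp),

the sum of the two per-class F1/2 terms — algebraically the macro-averaged
F1 (each term is half the class F1).  Precision and recall follow the
usual TP/(TP+FP) and TP/(TP+FN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import clone
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "precision_recall",
    "f_avg",
    "roc_auc",
    "evaluate_predictions",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts for one designated positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive=1) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t, pos_p = y_true == positive, y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
        )

    def swapped(self) -> "ConfusionCounts":
        """Counts with the positive/negative roles exchanged."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


def precision_recall(counts: ConfusionCounts) -> Tuple[float, float]:
    """(precision, recall) = (TP/(TP+FP), TP/(TP+FN))."""
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("precision undefined: TP + FP = 0")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("recall undefined: TP + FN = 0")
    return counts.tp / (counts.tp + counts.fp), counts.tp / (counts.tp + counts.fn)


def f_avg(counts_lp: ConfusionCounts, counts_nlp: ConfusionCounts) -> float:
    """Average F-score over the LP and NLP classes.

    Each class contributes P*R/(P+R), i.e. half its F1; a perfect
    classifier scores 0.5 + 0.5 = 1.  Symmetric under swapping the classes.
    """
    total = 0.0
    for counts in (counts_nlp, counts_lp):
        p, r = precision_recall(counts)
        if p + r == 0:
            raise UndefinedMetricError("F-score undefined: precision + recall = 0")
        total += p * r / (p + r)
    return total


def roc_auc(scores, labels, positive=1) -> Tuple[np.ndarray, float]:
    """ROC curve (threshold sweep) and trapezoidal AUC.

    Returns ``(points, auc)`` where ``points`` is an (n, 2) array of
    (FPR, TPR) pairs.  The AUC equals the normalized Mann-Whitney U
    statistic (pairwise concordance), which the tests exploit as an
    independent oracle.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise UndefinedMetricError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, pos_label=positive)
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


@dataclass
class MetricReport:
    """Bundle of patch-classification metrics (LP = positive class)."""

    precision_lp: float
    recall_lp: float
    precision_nlp: float
    recall_nlp: float
    f_avg: float
    accuracy: float
    confusion: ConfusionCounts
    auc: Optional[float] = None
    roc_points: Optional[np.ndarray] = None

    def as_dict(self) -> dict:
        d = {
            "precision_lp": self.precision_lp,
            "recall_lp": self.recall_lp,
            "precision_nlp": self.precision_nlp,
            "recall_nlp": self.recall_nlp,
            "f_avg": self.f_avg,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "confusion": {
                "tp": self.confusion.tp, "fp": self.confusion.fp,
                "fn": self.confusion.fn, "tn": self.confusion.tn,
            },
        }
        return d


def evaluate_predictions(
    y_true, y_pred, scores_lp=None, positive=1
) -> MetricReport:
    """Compute the full metric bundle from labels, predictions and scores."""
    counts_lp = ConfusionCounts.from_predictions(y_true, y_pred, positive=positive)
    counts_nlp = counts_lp.swapped()
    p_lp, r_lp = precision_recall(counts_lp)
    p_nlp, r_nlp = precision_recall(counts_nlp)
    auc_val, points = None, None
    if scores_lp is not None:
        points, auc_val = roc_auc(scores_lp, y_true, positive=positive)
    return MetricReport(
        precision_lp=p_lp, recall_lp=r_lp,
        precision_nlp=p_nlp, recall_nlp=r_nlp,
        f_avg=f_avg(counts_lp, counts_nlp),
        accuracy=(counts_lp.tp + counts_lp.tn) / counts_lp.total,
        confusion=counts_lp, auc=auc_val, roc_points=points,
    )


def cross_validate(
    X, y, estimator, n_folds: int = 8, seed: int = 0
) -> Tuple[List[MetricReport], MetricReport]:
    """Stratified k-fold cross-validation of a patch classifier.

    Each fold trains a fresh clone on (k-1)/k of the data and evaluates on
    the held-out 1/k (the 7:1 train/validation split for k=8).  Returns the
    per-fold reports and a report aggregated over the pooled out-of-fold
    predictions.
    """
    from .labelgen import LabeledPatchSet

    if isinstance(X, LabeledPatchSet):
        X, y = X.patches, X.labels
    X = np.asarray(X)
    y = np.asarray(y)
    if n_folds > len(y):
        raise ValueError(f"n_folds={n_folds} exceeds dataset size {len(y)}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reports: List[MetricReport] = []
    pooled_pred = np.empty_like(y)
    pooled_score = np.empty(len(y), dtype=float)
    for train_idx, val_idx in skf.split(X.reshape(len(X), -1), y):
        model = clone(estimator)
        model.fit(X[train_idx], y[train_idx])
        proba = model.predict_proba(X[val_idx])
        pred = model.classes_[(proba[:, 1] > 0.5).astype(int)]
        pooled_pred[val_idx] = pred
        pooled_score[val_idx] = proba[:, 1]
        reports.append(evaluate_predictions(y[val_idx], pred, proba[:, 1]))
    overall = evaluate_predictions(y, pooled_pred, pooled_score)
    return reports, overall
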