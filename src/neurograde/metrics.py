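"""Class-weighted cross-entropy and the evaluation suite.

Loss weighting for the imbalanced three-class problem uses normalized
per-class weights

    W_c = 1 - samples_c / samples_t

so that a rarer class contributes a larger weight; the weights always sum to
``n_classes - 1``.  For a sample of true class c the loss is
``-W_c * log P(c)`` with P obtained by softmax, and the total loss is the sum
of per-class terms (mean over a batch).

Evaluation is one-vs-rest from a confusion matrix with rows = true class and
columns = predicted class, in the fixed (LGG, HGG, HEALTHY) order: per-class
precision, recall, specificity and F1, plus macro F1 (unweighted mean),
weighted F1 (test-support weighted) and accuracy.  Fold aggregation reports
mean and sample (n-1) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import log_softmax, softmax
from sklearn.metrics import confusion_matrix as _sk_confusion

from .labels import CLASSES, CLASS_TO_INDEX, validate_label

__all__ = [
    "AggregateScores",
    "ClassWeights",
    "ClasswiseScores",
    "ConfusionMatrix",
    "CrossValReport",
    "LossBreakdown",
    "aggregate",
    "classwise_metrics",
    "classwise_report",
    "compute_class_weights",
    "confusion",
    "fold_mean_sd",
    "weighted_cross_entropy",
    "weighted_cross_entropy_grad",
]


# ---------------------------------------------------------------------------
# Loss


@dataclass(frozen=True)
class ClassWeights:
    """Normalized per-class loss weights W_c = 1 - samples_c / samples_t."""

    weights: np.ndarray
    class_counts: np.ndarray
    classes: tuple[str, ...] = CLASSES

    @property
    def total(self) -> int:
        return int(self.class_counts.sum())

    def __getitem__(self, label: str) -> float:
        return float(self.weights[self.classes.index(label)])


def compute_class_weights(class_counts, classes: tuple[str, ...] = CLASSES) -> ClassWeights:
    """Weights from per-class sample counts (mapping or sequence in class order)."""
    if isinstance(class_counts, Mapping):
        counts = np.array([class_counts.get(c, 0) for c in classes], dtype=np.int64)
    else:
        counts = np.asarray(class_counts, dtype=np.int64)
        if counts.shape != (len(classes),):
            raise ValueError(f"expected {len(classes)} counts, got {counts.shape}")
    if np.any(counts < 0):
        raise ValueError("class counts must be >= 0")
    total = counts.sum()
    if total == 0:
        raise ValueError("total sample count must be > 0")
    weights = 1.0 - counts / total
    if np.any(weights == 0.0):
        warnings.warn(
            "degenerate class weights: some class holds all samples (weight 0)",
            stacklevel=2,
        )
    return ClassWeights(weights=weights, class_counts=counts, classes=classes)


@dataclass(frozen=True)
class LossBreakdown:
    """Per-class loss terms and their total (mean over the batch)."""

    per_class: np.ndarray
    total: float
    classes: tuple[str, ...] = CLASSES


def _as_batch(logits, labels, n_classes: int):
    logits = np.asarray(logits, dtype=np.float64)
    if logits.ndim == 1:
        logits = logits[None, :]
    if logits.ndim != 2 or logits.shape[1] != n_classes:
        raise ValueError(f"logits must be (batch, {n_classes}), got {logits.shape}")
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    if isinstance(labels, str) or np.isscalar(labels):
        labels = [labels]
    idx = np.array([CLASS_TO_INDEX[validate_label(l)] if isinstance(l, str) else int(l)
                    for l in labels])
    if idx.shape[0] != logits.shape[0]:
        raise ValueError("one label per logits row required")
    if np.any((idx < 0) | (idx >= n_classes)):
        raise ValueError("label index out of range")
    return logits, idx


def weighted_cross_entropy(logits, true_labels, weights: ClassWeights) -> LossBreakdown:
    """Weighted cross-entropy of a batch of logits against true labels.

    ``per_class[c]`` is the mean over the batch of ``-W_c log P(c)``
    restricted to samples of true class c; ``total`` is their sum, equal to
    the mean per-sample loss.
    """
    n = len(weights.classes)
    logits, idx = _as_batch(logits, true_labels, n)
    logp = log_softmax(logits, axis=1)
    per_sample = -weights.weights[idx] * logp[np.arange(len(idx)), idx]
    per_class = np.zeros(n)
    np.add.at(per_class, idx, per_sample)
    per_class /= len(idx)
    return LossBreakdown(per_class=per_class, total=float(per_sample.mean()),
                         classes=weights.classes)


def weighted_cross_entropy_grad(logits, true_labels, weights: ClassWeights):
    """Loss plus its gradient w.r.t. the logits (for the training loop)."""
    n = len(weights.classes)
    logits, idx = _as_batch(logits, true_labels, n)
    breakdown = weighted_cross_entropy(logits, idx, weights)
    probs = softmax(logits, axis=1)
    onehot = np.zeros_like(probs)
    onehot[np.arange(len(idx)), idx] = 1.0
    grad = weights.weights[idx][:, None] * (probs - onehot) / len(idx)
    return breakdown, grad


# ---------------------------------------------------------------------------
# Confusion matrix and derived metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        n = len(self.classes)
        if c.shape != (n, n) or np.any(c < 0):
            raise ValueError(f"counts must be a nonnegative {n}x{n} matrix")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            raise ValueError("empty confusion matrix")
        return float(np.trace(self.counts) / self.total)

    def support(self, label: str) -> int:
        return int(self.counts[self.classes.index(label)].sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("class orders differ")
        return ConfusionMatrix(self.counts + other.counts, self.classes)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("true").to_csv(path)


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str],
              classes: tuple[str, ...] = CLASSES) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    for l in list(true_labels) + list(predicted_labels):
        if l not in classes:
            raise ValueError(f"unknown class label {l!r}; expected one of {classes}")
    counts = _sk_confusion(list(true_labels), list(predicted_labels), labels=list(classes))
    return ConfusionMatrix(counts=counts, classes=classes)


@dataclass(frozen=True)
class ClasswiseScores:
    precision: float
    recall: float
    specificity: float
    f1: float

    def to_dict(self) -> dict[str, float]:
        return {"precision": self.precision, "recall": self.recall,
                "specificity": self.specificity, "f1": self.f1}


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator computing {what}; returning 0", stacklevel=3)
        return 0.0
    return num / den


def classwise_metrics(cm: ConfusionMatrix, label: str) -> ClasswiseScores:
    """One-vs-rest precision, recall, specificity and F1 for one class."""
    i = cm.classes.index(label)
    c = cm.counts
    tp = c[i, i]
    fp = c[:, i].sum() - tp
    fn = c[i, :].sum() - tp
    tn = c.sum() - tp - fp - fn
    precision = _safe_div(tp, tp + fp, f"precision[{label}]")
    recall = _safe_div(tp, tp + fn, f"recall[{label}]")
    specificity = _safe_div(tn, tn + fp, f"specificity[{label}]")
    f1 = _safe_div(2 * precision * recall, precision + recall, f"F1[{label}]")
    return ClasswiseScores(float(precision), float(recall), float(specificity), float(f1))


def classwise_report(cm: ConfusionMatrix) -> dict[str, ClasswiseScores]:
    return {label: classwise_metrics(cm, label) for label in cm.classes}


@dataclass(frozen=True)
class AggregateScores:
    macro_f1: float
    weighted_f1: float
    accuracy: float


def aggregate(cm: ConfusionMatrix) -> AggregateScores:
    """Macro F1, support-weighted F1 and accuracy from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    f1s = np.array([classwise_metrics(cm, c).f1 for c in cm.classes])
    supports = cm.counts.sum(axis=1)
    return AggregateScores(
        macro_f1=float(f1s.mean()),
        weighted_f1=float((f1s * supports).sum() / supports.sum()),
        accuracy=cm.accuracy,
    )


def fold_mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation over fold values."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least 2 fold values for mean +/- SD")
    return float(v.mean()), float(v.std(ddof=1))


# ---------------------------------------------------------------------------
# Cross-validation report


@dataclass
class CrossValReport:
    """Per-fold confusion matrices and reports plus pooled aggregates.

    Macro and weighted F1 are computed on the pooled (summed) confusion
    matrix; the per-fold mean accuracy is also reported alongside.
    """

    fold_confusions: list[ConfusionMatrix]
    fold_reports: list[dict[str, ClasswiseScores]] = field(default_factory=list)
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self):
        if not self.fold_reports:
            self.fold_reports = [classwise_report(cm) for cm in self.fold_confusions]

    @property
    def n_folds(self) -> int:
        return len(self.fold_confusions)

    @property
    def pooled(self) -> ConfusionMatrix:
        pooled = self.fold_confusions[0]
        for cm in self.fold_confusions[1:]:
            pooled = pooled + cm
        return pooled

    def per_class_f1(self) -> dict[str, tuple[float, float]]:
        return {
            c: fold_mean_sd([rep[c].f1 for rep in self.fold_reports])
            for c in self.classes
        }

    @property
    def macro_f1(self) -> float:
        return aggregate(self.pooled).macro_f1

    @property
    def weighted_f1(self) -> float:
        return aggregate(self.pooled).weighted_f1

    @property
    def pooled_accuracy(self) -> float:
        return self.pooled.accuracy

    @property
    def mean_fold_accuracy(self) -> float:
        return float(np.mean([cm.accuracy for cm in self.fold_confusions]))

    def to_dict(self) -> dict:
        per_class = {
            c: {"mean_f1": m, "sd_f1": s} for c, (m, s) in self.per_class_f1().items()
        }
        return {
            "n_folds": self.n_folds,
            "folds": [
                {
                    "confusion": cm.counts.tolist(),
                    "accuracy": cm.accuracy,
                    "classwise": {c: r.to_dict() for c, r in rep.items()},
                }
                for cm, rep in zip(self.fold_confusions, self.fold_reports)
            ],
            "per_class_f1": per_class,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "pooled_accuracy": self.pooled_accuracy,
            "mean_fold_accuracy": self.mean_fold_accuracy,
            "pooled_confusion": self.pooled.counts.tolist(),
            "classes": list(self.classes),
        }
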