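"""Confusion-matrix metrics and ROC analysis for encoding-scheme evaluation.

The scalar suite is the nine-score panel used to compare DNA encodings:
accuracy, precision, recall, specificity, F1, CSI (classification success
index = precision + recall - 1), G-mean (sqrt of recall x specificity),
Matthews correlation and Cohen's kappa — all defined on binary TP/FP/TN/FN
counts, macro-averaged one-vs-rest in the multi-class case. ROC-AUC is
offered per-class, micro-averaged (pool all one-vs-rest decisions) and
macro-averaged (average per-class curves with equal weight).

Qualitative interpretation bins for AUC (no distinction / poor / acceptable /
great / outstanding) and kappa (no / slight / fair / moderate / substantial /
almost perfect / perfect agreement) follow the conventional tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.preprocessing import label_binarize


class MetricError(ValueError):
    """Raised on undefined metric evaluations in strict mode."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary (or one-vs-rest) confusion-matrix tallies."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")
        if self.total < 1:
            raise ValueError("at least one sample is required")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    true_labels: Sequence, predicted_labels: Sequence, positive_class
) -> ConfusionCounts:
    """One-vs-rest confusion counts for ``positive_class``."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label lists differ in length: {len(true_labels)} vs {len(predicted_labels)}"
        )
    if len(true_labels) == 0:
        raise ValueError("label lists are empty")
    universe = set(true_labels) | set(predicted_labels)
    if positive_class not in universe:
        raise ValueError(f"positive_class {positive_class!r} absent from label universe")
    tp = fp = tn = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        t_pos, p_pos = t == positive_class, p == positive_class
        if t_pos and p_pos:
            tp += 1
        elif not t_pos and p_pos:
            fp += 1
        elif t_pos and not p_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, name: str, strict: bool) -> float:
    if den == 0:
        if strict:
            raise MetricError(f"{name} undefined: zero denominator")
        warnings.warn(f"{name} has zero denominator; returning 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    return (c.tp + c.tn) / c.total


def precision(c: ConfusionCounts, strict: bool = False) -> float:
    """TP / (TP + FP)."""
    return _ratio(c.tp, c.tp + c.fp, "precision", strict)


def recall(c: ConfusionCounts, strict: bool = False) -> float:
    """TP / (TP + FN), the true-positive rate."""
    return _ratio(c.tp, c.tp + c.fn, "recall", strict)


def specificity(c: ConfusionCounts, strict: bool = False) -> float:
    """TN / (TN + FP), the true-negative rate."""
    return _ratio(c.tn, c.tn + c.fp, "specificity", strict)


def f1(c: ConfusionCounts, strict: bool = False) -> float:
    """Harmonic mean of precision and recall."""
    p, r = precision(c, strict), recall(c, strict)
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def csi(c: ConfusionCounts, strict: bool = False) -> float:
    """Classification success index: precision + recall - 1, in [-1, 1]."""
    return precision(c, strict) + recall(c, strict) - 1.0


def gmean(c: ConfusionCounts, strict: bool = False) -> float:
    """Geometric mean of recall and specificity: sqrt(recall * specificity)."""
    return math.sqrt(recall(c, strict) * specificity(c, strict))


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    den2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if den2 == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(den2)


def kappa(c: ConfusionCounts) -> float:
    """Binary Cohen's kappa: 2(TP*TN - FP*FN) / [(TP+FP)(FP+TN) + (TP+FN)(FN+TN)]."""
    den = (c.tp + c.fp) * (c.fp + c.tn) + (c.tp + c.fn) * (c.fn + c.tn)
    if den == 0:
        raise MetricError("kappa undefined: zero denominator")
    return 2.0 * (c.tp * c.tn - c.fp * c.fn) / den


@dataclass
class RocCurve:
    """An ROC polyline with its averaging mode."""

    fpr: np.ndarray
    tpr: np.ndarray
    mode: str  # "per-class" | "micro" | "macro"
    class_label: object | None = None


def _binary_roc(y_true01: np.ndarray, scores: np.ndarray, mode: str, cls=None) -> tuple[RocCurve, float]:
    fpr, tpr, _ = _sk_roc_curve(y_true01, scores)
    return RocCurve(fpr=fpr, tpr=tpr, mode=mode, class_label=cls), float(_trapezoid_auc(fpr, tpr))


def roc_auc(
    true_labels: Sequence,
    scores: np.ndarray,
    mode: str = "per-class",
    classes: Sequence | None = None,
    positive_class=None,
) -> tuple[RocCurve, float]:
    """ROC curve and AUC under the requested averaging mode.

    ``scores`` is either a 1-D positive-class score vector (binary) or an
    (n_samples, n_classes) column-per-class matrix. Class order is
    alphabetical unless ``classes`` is given. Micro averaging pools every
    one-vs-rest (label, score) pair before building one curve; macro
    averaging builds per-class curves and averages their AUCs (and
    interpolated TPRs) with equal class weight, skipping — with a warning —
    classes absent from the truth.
    """
    true_labels = list(true_labels)
    scores = np.asarray(scores, dtype=float)
    if classes is None:
        classes = sorted(set(true_labels))
    classes = list(classes)

    if scores.ndim == 1:
        if positive_class is None:
            if len(classes) != 2:
                raise ValueError("1-D scores require 2 classes or an explicit positive_class")
            positive_class = classes[0]  # alphabetical class order; first is positive
        y = np.asarray([1 if t == positive_class else 0 for t in true_labels])
        return _binary_roc(y, scores, "per-class", positive_class)

    if scores.shape != (len(true_labels), len(classes)):
        raise ValueError(
            f"scores shape {scores.shape} does not match ({len(true_labels)}, {len(classes)})"
        )
    onehot = label_binarize(true_labels, classes=classes)
    if onehot.shape[1] == 1:  # sklearn collapses the binary case
        onehot = np.hstack([1 - onehot, onehot])

    if mode == "micro":
        return _binary_roc(onehot.ravel(), scores.ravel(), "micro")
    if mode == "macro":
        grid = np.linspace(0.0, 1.0, 101)
        mean_tpr = np.zeros_like(grid)
        aucs = []
        present = 0
        for k, cls in enumerate(classes):
            if onehot[:, k].sum() == 0:
                warnings.warn(f"class {cls!r} absent from true labels; skipped in macro average",
                              RuntimeWarning, stacklevel=2)
                continue
            curve, a = _binary_roc(onehot[:, k], scores[:, k], "per-class", cls)
            mean_tpr += np.interp(grid, curve.fpr, curve.tpr)
            aucs.append(a)
            present += 1
        if present == 0:
            raise ValueError("no class present in true labels")
        mean_tpr /= present
        return RocCurve(fpr=grid, tpr=mean_tpr, mode="macro"), float(np.mean(aucs))
    if mode == "per-class":
        if positive_class is None:
            raise ValueError("per-class mode on a score matrix needs positive_class")
        k = classes.index(positive_class)
        return _binary_roc(onehot[:, k], scores[:, k], "per-class", positive_class)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------- interpretation

_AUC_BINS = [
    (0.50, "No distinction"),
    (0.70, "Poor classification"),
    (0.80, "Acceptable classification"),
    (0.90, "Great classification"),
    (1.00 + 1e-12, "Outstanding classification"),
]

_KAPPA_BINS = [
    (0.10, "No agreement"),
    (0.21, "Slight agreement"),
    (0.41, "Fair agreement"),
    (0.61, "Moderate agreement"),
    (0.81, "Substantial agreement"),
    (1.00, "Almost perfect agreement"),
]


def interpret_auc(auc_value: float) -> str:
    """Qualitative AUC category (half-open bins, upper edge exclusive)."""
    if not 0.0 <= auc_value <= 1.0:
        raise ValueError(f"AUC must be in [0, 1], got {auc_value}")
    for upper, label in _AUC_BINS:
        if auc_value < upper:
            return label
    return _AUC_BINS[-1][1]


def interpret_kappa(k: float) -> str:
    """Qualitative agreement category for a kappa coefficient.

    Negative or near-zero values (< 0.10) read as no agreement; 1.0 exactly
    is perfect agreement.
    """
    if k >= 1.0:
        return "Perfect agreement"
    for upper, label in _KAPPA_BINS:
        if k < upper:
            return label
    return "Perfect agreement"


# ---------------------------------------------------------------- aggregation

@dataclass
class MetricReport:
    """The nine-score panel plus micro/macro AUC for one evaluation."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    csi: float
    gmean: float
    mcc: float
    kappa: float
    auc_micro: float | None = None
    auc_macro: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def interpretations(self) -> dict[str, str]:
        out = {"kappa": interpret_kappa(self.kappa)}
        if self.auc_macro is not None:
            out["auc_macro"] = interpret_auc(self.auc_macro)
        if self.auc_micro is not None:
            out["auc_micro"] = interpret_auc(self.auc_micro)
        return out


_SCALARS = (precision, recall, specificity, f1, csi, gmean)


def metric_report(
    true_labels: Sequence,
    predicted_labels: Sequence,
    scores: np.ndarray | None = None,
    positive_class=None,
    strict: bool = False,
) -> MetricReport:
    """Aggregate the full panel from labels (and optionally scores).

    Binary problems use the positive class directly (alphabetically first
    class by default). Multi-class problems macro-average the one-vs-rest
    scalar metrics; accuracy is the overall fraction correct in both cases.
    AUC fields are filled only when ``scores`` are provided.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    classes = sorted(set(true_labels))
    if len(classes) < 2:
        raise ValueError("at least two classes must be present in the true labels")

    n_correct = sum(t == p for t, p in zip(true_labels, predicted_labels))
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists differ in length")
    acc = n_correct / len(true_labels)

    if len(classes) == 2:
        pos = positive_class if positive_class is not None else classes[0]
        counts = [confusion(true_labels, predicted_labels, pos)]
    else:
        counts = [confusion(true_labels, predicted_labels, cls) for cls in classes]

    panel = {
        fn.__name__: float(np.mean([fn(c, strict) for c in counts])) for fn in _SCALARS
    }
    panel["mcc"] = float(np.mean([mcc(c) for c in counts]))
    panel["kappa"] = float(np.mean([kappa(c) for c in counts]))

    auc_micro = auc_macro = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if scores.ndim == 1:
            pos = positive_class if positive_class is not None else classes[0]
            score_mat = np.column_stack(
                [scores if cls == pos else 1.0 - scores for cls in classes]
            )
        else:
            score_mat = scores
        _, auc_micro = roc_auc(true_labels, score_mat, mode="micro", classes=classes)
        _, auc_macro = roc_auc(true_labels, score_mat, mode="macro", classes=classes)

    return MetricReport(accuracy=acc, auc_micro=auc_micro, auc_macro=auc_macro, **panel)
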