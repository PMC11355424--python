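"""Multiclass evaluation measures for imbalanced classification.

The headline measure is a weighted F1 defined as the harmonic mean of the
class-share-weighted precision and the class-share-weighted recall:

    P_i = TP_i / (TP_i + FP_i)          R_i = TP_i / (TP_i + FN_i)
    P_w = Σ_i w_i P_i                   R_w = Σ_i w_i R_i
    weighted F1 = 2 P_w R_w / (P_w + R_w)

with w_i the share of class *i* among the true labels. Note this is NOT
the conventional "weighted-average of per-class F1 scores"; the two
disagree whenever per-class precision and recall are unbalanced.

The multiclass Matthews correlation coefficient is computed from one-hot
truth/prediction matrices X, Y as cov(X,Y) / sqrt(cov(X,X) · cov(Y,Y))
(the Gorodkin R_K statistic). ACC is plain accuracy; macro F1 is the
unweighted mean of per-class F1. Ratios with zero denominator are taken
as 0 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ValidationError


@dataclass
class ClassCounts:
    """Per-class confusion counts: TP_i, FP_i, FN_i and class shares w_i."""

    classes: list
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self):
        self.tp = np.asarray(self.tp, dtype=np.int64)
        self.fp = np.asarray(self.fp, dtype=np.int64)
        self.fn = np.asarray(self.fn, dtype=np.int64)
        if not (len(self.classes) == len(self.tp) == len(self.fp) == len(self.fn)):
            raise ValidationError("per-class count arrays must align with classes")
        if np.any(self.tp < 0) or np.any(self.fp < 0) or np.any(self.fn < 0):
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return int((self.tp + self.fn).sum())

    @property
    def weights(self) -> np.ndarray:
        """w_i: true class-i share of all samples."""
        n = self.n
        if n == 0:
            raise ValidationError("no samples")
        return (self.tp + self.fn) / n


@dataclass
class MetricSet:
    """The evaluation quadruple reported for every classifier."""

    acc: float
    mcc: float
    macro_f1: float
    weighted_f1: float

    def __post_init__(self):
        for name in ("acc", "macro_f1", "weighted_f1"):
            v = getattr(self, name)
            if np.isnan(v) or not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if np.isnan(self.mcc) or not (-1.0 <= self.mcc <= 1.0):
            raise ValidationError(f"mcc={self.mcc} outside [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "mcc": self.mcc,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
        }


def _check_lengths(true_labels, predicted_labels):
    if len(true_labels) != len(predicted_labels):
        raise ValidationError(
            f"label length mismatch: {len(true_labels)} vs {len(predicted_labels)}"
        )
    if len(true_labels) == 0:
        raise ValidationError("no samples")


def confusion(true_labels, predicted_labels, classes=None) -> ClassCounts:
    """Exact per-class TP/FP/FN counts.

    ``classes`` fixes the class universe (and its order); by default it is
    the union of labels in first-appearance order over truth then
    predictions.
    """
    _check_lengths(true_labels, predicted_labels)
    if classes is None:
        classes = list(dict.fromkeys(list(true_labels) + list(predicted_labels)))
    else:
        classes = list(classes)
        stray = set(true_labels) | set(predicted_labels)
        if stray - set(classes):
            raise ValidationError(f"labels outside class universe: {sorted(stray - set(classes))}")
    lut = {c: i for i, c in enumerate(classes)}
    L = len(classes)
    tp = np.zeros(L, dtype=np.int64)
    fp = np.zeros(L, dtype=np.int64)
    fn = np.zeros(L, dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        ti, pi = lut[t], lut[p]
        if ti == pi:
            tp[ti] += 1
        else:
            fn[ti] += 1
            fp[pi] += 1
    return ClassCounts(classes=classes, tp=tp, fp=fp, fn=fn)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    mask = den > 0
    out[mask] = num[mask] / den[mask]
    return out


def precision_per_class(counts: ClassCounts) -> np.ndarray:
    return _safe_div(counts.tp, counts.tp + counts.fp)


def recall_per_class(counts: ClassCounts) -> np.ndarray:
    return _safe_div(counts.tp, counts.tp + counts.fn)


def weighted_f1(counts: ClassCounts) -> float:
    """Harmonic mean of class-share-weighted precision and recall."""
    w = counts.weights
    p_w = float(np.sum(w * precision_per_class(counts)))
    r_w = float(np.sum(w * recall_per_class(counts)))
    if p_w + r_w == 0:
        return 0.0
    return 2.0 * p_w * r_w / (p_w + r_w)


def macro_f1(counts: ClassCounts) -> float:
    """Unweighted mean over classes of per-class F1 (0/0 taken as 0)."""
    p = precision_per_class(counts)
    r = recall_per_class(counts)
    f1 = _safe_div(2.0 * p * r, p + r)
    return float(f1.mean())


def accuracy(true_labels, predicted_labels) -> float:
    _check_lengths(true_labels, predicted_labels)
    matches = sum(t == p for t, p in zip(true_labels, predicted_labels))
    return matches / len(true_labels)


def multiclass_mcc(true_labels, predicted_labels, classes=None) -> float:
    """Matthews correlation from one-hot matrices.

    X (truth) and Y (predictions) are n × L one-hot; with column-centred
    matrices, MCC = <X,Y> / sqrt(<X,X> <Y,Y>). A zero denominator (all
    samples in one true class, or constant predictions) yields 0.
    """
    _check_lengths(true_labels, predicted_labels)
    if classes is None:
        classes = list(dict.fromkeys(list(true_labels) + list(predicted_labels)))
    lut = {c: i for i, c in enumerate(classes)}
    n, L = len(true_labels), len(classes)
    X = np.zeros((n, L))
    Y = np.zeros((n, L))
    X[np.arange(n), [lut[t] for t in true_labels]] = 1.0
    Y[np.arange(n), [lut[p] for p in predicted_labels]] = 1.0
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    cov_xy = float(np.sum(Xc * Yc))
    cov_xx = float(np.sum(Xc * Xc))
    cov_yy = float(np.sum(Yc * Yc))
    if cov_xx == 0 or cov_yy == 0:
        return 0.0
    return cov_xy / np.sqrt(cov_xx * cov_yy)


def evaluate(true_labels, predicted_labels, classes=None) -> MetricSet:
    """Compute the full metric quadruple on one truth/prediction pair."""
    counts = confusion(true_labels, predicted_labels, classes=classes)
    return MetricSet(
        acc=accuracy(true_labels, predicted_labels),
        mcc=multiclass_mcc(true_labels, predicted_labels, classes=classes),
        macro_f1=macro_f1(counts),
        weighted_f1=weighted_f1(counts),
    )
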