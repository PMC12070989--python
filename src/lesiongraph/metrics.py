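"""Segmentation and classification metrics: Dice/IoU, BCE, per-class and
macro precision/recall/F1, confusion matrix, one-vs-rest ROC-AUC, and the
class imbalance ratio."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ShapeError

__all__ = [
    "SegScores",
    "MetricsReport",
    "IRResult",
    "segmentation_scores",
    "bce_loss",
    "confusion_matrix",
    "classification_report",
    "imbalance_ratio",
    "roc_auc_ovr",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (so 1.205 -> 1.21, unlike bankers' rounding)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# segmentation


@dataclass(frozen=True)
class SegScores:
    dice: float
    iou: float
    precision: float
    recall: float

    def __post_init__(self):
        for name in ("dice", "iou", "precision", "recall"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ShapeError(f"{name} out of [0, 1]: {v}")
        # algebraic identity dice = 2*iou/(1+iou)
        assert abs(self.dice - 2 * self.iou / (1 + self.iou)) < 1e-9 or (
            self.iou == 0 and self.dice == 0
        )


def segmentation_scores(pred_mask: np.ndarray, gt_mask: np.ndarray) -> SegScores:
    """Pixelwise overlap scores between two binary masks.

    Conventions: both masks empty -> every score 1; any other 0/0 denominator
    (e.g. empty ground truth for recall) also resolves to 1, because there was
    nothing to miss.
    """
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ShapeError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    for arr, name in ((pred, "pred_mask"), (gt, "gt_mask")):
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1, False, True)).all():
            raise ShapeError(f"{name} must be binary, found values {vals}")
    pred = pred.astype(bool)
    gt = gt.astype(bool)
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())

    def safe(num, den):
        return num / den if den > 0 else 1.0

    return SegScores(
        dice=safe(2 * tp, 2 * tp + fp + fn),
        iou=safe(tp, tp + fp + fn),
        precision=safe(tp, tp + fp),
        recall=safe(tp, tp + fn),
    )


def bce_loss(pred_probs: np.ndarray, gt_mask: np.ndarray) -> float:
    """Mean per-pixel binary cross-entropy, probabilities clamped at 1e-12."""
    p = np.asarray(pred_probs, dtype=float)
    y = np.asarray(gt_mask)
    if p.shape != y.shape:
        raise ShapeError(f"shapes differ: {p.shape} vs {y.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ShapeError("predicted probabilities must lie in [0, 1]")
    y = y.astype(float)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


# ---------------------------------------------------------------------------
# classification


def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """Entry (r, c) counts items of true class r predicted as class c."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ShapeError("label vectors differ in length")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ShapeError(f"labels out of range [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics, macro averages, confusion matrix, AUC.

    ``per_class_accuracy`` is the one-vs-rest accuracy (TP+TN)/N per class;
    ``accuracy`` is the plain multi-class accuracy.  Macro values are the
    arithmetic means of the per-class vectors.  ``flags`` lists classes whose
    recall or AUC was undefined on this evaluation set.
    """

    n_classes: int
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    per_class_accuracy: np.ndarray
    accuracy: float
    macro_f1: float
    macro_accuracy: float
    auc: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        assert self.confusion.sum() >= 0
        assert abs(self.macro_f1 - float(np.mean(self.f1))) < 1e-12
        assert abs(self.macro_accuracy - float(np.mean(self.per_class_accuracy))) < 1e-12

    def to_dict(self) -> dict:
        d = {
            "n_classes": self.n_classes,
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "per_class_accuracy": self.per_class_accuracy.tolist(),
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "macro_accuracy": self.macro_accuracy,
            "flags": self.flags,
        }
        if self.auc is not None:
            d["auc"] = [None if np.isnan(a) else float(a) for a in self.auc]
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def classification_report(
    true_labels,
    predicted_labels,
    probabilities: np.ndarray | None = None,
    n_classes: int | None = None,
) -> MetricsReport:
    """Per-class precision/recall/F1 (one-vs-rest), accuracy, macro averages.

    An absent true class gets recall 0 with a flag; per-class metrics with a
    0/0 denominator resolve to 0 (flagged).  AUC per class comes from
    ``roc_auc_ovr`` when a probability matrix is supplied.
    """
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if probabilities is not None:
        probabilities = np.asarray(probabilities, dtype=float)
        if probabilities.shape[0] != t.shape[0]:
            raise ShapeError("probabilities and labels disagree in length")
        if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
            raise ShapeError("probability rows must sum to 1")
        if n_classes is None:
            n_classes = probabilities.shape[1]
    if n_classes is None:
        n_classes = int(max(t.max(), p.max())) + 1
    cm = confusion_matrix(t, p, n_classes)
    n = int(cm.sum())
    flags: list[str] = []
    precision = np.zeros(n_classes)
    recall = np.zeros(n_classes)
    f1 = np.zeros(n_classes)
    pc_acc = np.zeros(n_classes)
    for c in range(n_classes):
        tp = int(cm[c, c])
        fp = int(cm[:, c].sum() - tp)
        fn = int(cm[c, :].sum() - tp)
        tn = n - tp - fp - fn
        precision[c] = tp / (tp + fp) if tp + fp > 0 else 0.0
        if tp + fp == 0:
            flags.append(f"class {c}: precision undefined (no predictions), reported 0")
        if tp + fn > 0:
            recall[c] = tp / (tp + fn)
        else:
            recall[c] = 0.0
            flags.append(f"class {c}: recall undefined (absent from true labels), reported 0")
        denom = precision[c] + recall[c]
        f1[c] = 2 * precision[c] * recall[c] / denom if denom > 0 else 0.0
        pc_acc[c] = (tp + tn) / n if n > 0 else 0.0
    auc = None
    if probabilities is not None:
        auc = np.full(n_classes, np.nan)
        for c in range(n_classes):
            pos = t == c
            if pos.any() and (~pos).any():
                auc[c] = roc_auc_ovr(t, probabilities, c)
            else:
                flags.append(f"class {c}: AUC undefined (degenerate one-vs-rest split)")
    return MetricsReport(
        n_classes=n_classes,
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        per_class_accuracy=pc_acc,
        accuracy=float(np.trace(cm) / n) if n else 0.0,
        macro_f1=float(np.mean(f1)),
        macro_accuracy=float(np.mean(pc_acc)),
        auc=auc,
        flags=flags,
    )


class IRResult(NamedTuple):
    exact: float
    rounded: float


def imbalance_ratio(class_counts: Sequence[int]) -> IRResult:
    """Largest class count over smallest; exact and half-up 2-decimal values."""
    counts = [int(c) for c in class_counts]
    if not counts or any(c <= 0 for c in counts):
        raise ShapeError(f"class counts must be positive, got {class_counts}")
    exact = max(counts) / min(counts)
    return IRResult(exact=exact, rounded=round_half_up(exact, 2))


def roc_auc_ovr(true_labels, probabilities, class_index: int) -> float:
    """One-vs-rest ROC-AUC by trapezoidal integration over score thresholds.

    Ties in scores are grouped into a single threshold, which makes the result
    equal to the Mann-Whitney rank statistic with ties counted 1/2.  Returns
    NaN when one of the binarized classes is absent.
    """
    t = np.asarray(true_labels, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    scores = probabilities[:, class_index] if probabilities.ndim == 2 else probabilities
    pos = t == class_index
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = pos[order].astype(float)
    # group tied scores: keep the last index of each distinct value
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    tps = np.cumsum(y)[idx]
    fps = (idx + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))
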