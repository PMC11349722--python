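"""Segmentation evaluation measures computed from confusion counts.

Per-class counts feed the six headline measures (IoU, Dice, accuracy,
mIoU, mDice, MPA) plus precision/recall/F1 for the foreground (plaque)
class.  Formulas, with TP/FP/FN/TN the per-class pixel counts:

    IoU   = TP / (TP + FP + FN)          Dice = 2·TP / (2·TP + FP + FN)
    acc   = (TP + TN) / total            PA_c = TP_c / (TP_c + FN_c)
    mIoU  = mean_c IoU_c                 MPA  = mean_c PA_c
    prec  = TP / (TP + FP)               rec  = TP / (TP + FN)

Degenerate classes follow an explicit policy: a class absent from both
prediction and target scores 1.0 (vacuously perfect), a class absent
from the target but predicted scores 0.0.

Dataset-level aggregation is *micro* (counts summed over images) by
default; *macro* (mean of per-image reports) is available and labeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DataError

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "compute_metrics",
           "micro_report", "macro_report"]


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN/TN pixel counts (arrays of length n_classes)."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass
class MetricsReport:
    """The evaluation scalars (fractions in [0,1]) plus per-class values."""

    iou: float
    dice: float
    accuracy: float
    miou: float
    mdice: float
    mpa: float
    precision: float
    recall: float
    f1: float
    per_class_iou: np.ndarray
    per_class_dice: np.ndarray
    per_class_pa: np.ndarray

    SCALARS = ("iou", "dice", "accuracy", "miou", "mdice", "mpa",
               "precision", "recall", "f1")

    def as_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        d = {k: round(scale * getattr(self, k), 2) if percent
             else getattr(self, k) for k in self.SCALARS}
        for k in ("per_class_iou", "per_class_dice", "per_class_pa"):
            vals = np.asarray(getattr(self, k)) * scale
            d[k] = [round(float(v), 2) if percent else float(v) for v in vals]
        return d

    def format_percent(self) -> str:
        """Render the scalar metrics as the conventional percent table."""
        return "  ".join(
            f"{k}={100 * getattr(self, k):.2f}%" for k in self.SCALARS
        )


def confusion(pred, target, n_classes: int = 2) -> ConfusionCounts:
    """Exact integer confusion counts per class."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise DataError(
            f"prediction shape {pred.shape} != target shape {target.shape}"
        )
    if pred.min() < 0 or pred.max() >= n_classes or target.min() < 0 \
            or target.max() >= n_classes:
        raise DataError(f"labels must lie in [0, {n_classes})")
    joint = np.bincount(
        (target.ravel() * n_classes + pred.ravel()).astype(np.int64),
        minlength=n_classes * n_classes,
    ).reshape(n_classes, n_classes)  # joint[t, p]
    tp = np.diag(joint).astype(np.int64)
    fp = joint.sum(axis=0) - tp
    fn = joint.sum(axis=1) - tp
    tn = joint.sum() - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _safe_ratio(num, den, tp, fp, fn, empty_both: float, empty_target: float):
    """Elementwise num/den with the degenerate-class policy applied."""
    num, den = np.asarray(num, float), np.asarray(den, float)
    out = np.zeros_like(num)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    vacuous = (tp + fp + fn) == 0          # absent from pred and target
    absent_target = ((tp + fn) == 0) & ~vacuous
    out[~ok & vacuous] = empty_both
    out[~ok & absent_target] = empty_target
    return out


def compute_metrics(counts: ConfusionCounts, foreground: int = 1,
                    empty_both: float = 1.0,
                    empty_target: float = 0.0) -> MetricsReport:
    """All evaluation measures from one set of confusion counts."""
    if counts.total <= 0:
        raise DataError("confusion counts are empty")
    tp, fp, fn, tn = (x.astype(float) for x in
                      (counts.tp, counts.fp, counts.fn, counts.tn))
    itp, ifp, ifn = counts.tp, counts.fp, counts.fn
    iou = _safe_ratio(tp, tp + fp + fn, itp, ifp, ifn, empty_both, empty_target)
    dice = _safe_ratio(2 * tp, 2 * tp + fp + fn, itp, ifp, ifn,
                       empty_both, empty_target)
    pa = _safe_ratio(tp, tp + fn, itp, ifp, ifn, empty_both, empty_target)
    fg = foreground
    precision = _safe_ratio(tp, tp + fp, itp, ifp, ifn,
                            empty_both, empty_target)[fg]
    recall = pa[fg]
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    accuracy = float((tp[fg] + tn[fg]) / counts.total)
    return MetricsReport(
        iou=float(iou[fg]), dice=float(dice[fg]), accuracy=accuracy,
        miou=float(iou.mean()), mdice=float(dice.mean()), mpa=float(pa.mean()),
        precision=float(precision), recall=float(recall), f1=float(f1),
        per_class_iou=iou, per_class_dice=dice, per_class_pa=pa,
    )


def micro_report(counts: Sequence[ConfusionCounts], **kwargs) -> MetricsReport:
    """Metrics on summed confusion counts (pixel-weighted)."""
    if not counts:
        raise DataError("no confusion counts to aggregate")
    total = counts[0]
    for c in counts[1:]:
        total = total + c
    return compute_metrics(total, **kwargs)


def macro_report(counts: Sequence[ConfusionCounts], **kwargs) -> MetricsReport:
    """Unweighted mean of per-image metric reports."""
    if not counts:
        raise DataError("no confusion counts to aggregate")
    reports = [compute_metrics(c, **kwargs) for c in counts]
    mean = lambda key: float(np.mean([getattr(r, key) for r in reports]))
    arr_mean = lambda key: np.mean([getattr(r, key) for r in reports], axis=0)
    return MetricsReport(
        **{k: mean(k) for k in MetricsReport.SCALARS},
        per_class_iou=arr_mean("per_class_iou"),
        per_class_dice=arr_mean("per_class_dice"),
        per_class_pa=arr_mean("per_class_pa"),
    )
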