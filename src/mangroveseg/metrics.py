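"""Accuracy assessment from a pixel confusion matrix.

All metrics — overall accuracy, per-class IoU (Jaccard) and per-class F1 —
are derived from one C x C confusion matrix with rows indexing the
reference class and columns the predicted class, so every reported number
is recomputable from the same pixel counts.

Per-class F1 is the harmonic mean of hard-count precision and recall and
satisfies the Dice-Jaccard identity F1 = 2*IoU / (1 + IoU) exactly. Macro
means are unweighted over the defined classes; classes absent from both
reference and prediction are flagged undefined (NaN) and excluded, never
silently counted as zero. A micro-averaged F1 (global counts) is reported
alongside the macro mean because aggregation conventions differ between
published tables.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .legend import DEFAULT_LEGEND
from .raster import LabelMask


@dataclass
class ConfusionMatrix:
    """counts[i, j] = pixels with reference class i predicted as class j."""

    counts: np.ndarray
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        if self.class_names is not None and len(self.class_names) != len(self.counts):
            raise ValueError("one class name per row required")

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if other.num_classes != self.num_classes:
            raise ValueError("cannot add confusion matrices of different size")
        return ConfusionMatrix(self.counts + other.counts, self.class_names)


def confusion_matrix(pred: LabelMask | np.ndarray, ref: LabelMask | np.ndarray,
                     num_classes: int | None = None,
                     class_names: tuple[str, ...] | None = None) -> ConfusionMatrix:
    """Count (reference, prediction) pixel pairs; NaN/no-data excluded upstream."""
    p = pred.classes if isinstance(pred, LabelMask) else np.asarray(pred)
    r = ref.classes if isinstance(ref, LabelMask) else np.asarray(ref)
    if p.shape != r.shape:
        raise ValueError(f"prediction {p.shape} and reference {r.shape} shapes differ")
    if num_classes is None:
        if isinstance(ref, LabelMask):
            num_classes = ref.legend.num_classes
        else:
            num_classes = int(max(p.max(initial=0), r.max(initial=0))) + 1
    if class_names is None and isinstance(ref, LabelMask):
        class_names = ref.legend.names
    p = p.ravel().astype(np.int64)
    r = r.ravel().astype(np.int64)
    if p.size and (p.min() < 0 or p.max() >= num_classes or r.min() < 0 or r.max() >= num_classes):
        raise ValueError(f"class values outside [0, {num_classes - 1}]")
    counts = np.bincount(r * num_classes + p, minlength=num_classes**2)
    return ConfusionMatrix(counts.reshape(num_classes, num_classes), class_names)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of pixels whose prediction equals the reference: trace/total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def _tp_fp_fn(cm: ConfusionMatrix):
    tp = np.diag(cm.counts).astype(np.float64)
    fp = cm.counts.sum(axis=0) - tp  # predicted k but reference differs
    fn = cm.counts.sum(axis=1) - tp  # reference k but predicted differs
    return tp, fp, fn


def per_class_iou(cm: ConfusionMatrix) -> tuple[np.ndarray, float]:
    """Per-class TP/(TP+FP+FN) and the unweighted mean over defined classes.

    A class absent from both reference and prediction has an empty union;
    its IoU is NaN and it is excluded from the mean.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn = _tp_fp_fn(cm)
    union = tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, tp / union, np.nan)
    return iou, float(np.nanmean(iou))


def per_class_f1(cm: ConfusionMatrix) -> tuple[np.ndarray, float]:
    """Per-class harmonic mean of hard-count precision and recall, with the
    unweighted mean over defined classes (NaN where precision+recall = 0)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn = _tp_fp_fn(cm)
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, np.nan)
    return f1, float(np.nanmean(f1))


def micro_f1(cm: ConfusionMatrix) -> float:
    """F1 from globally pooled counts; for single-label per-pixel data this
    equals overall accuracy."""
    tp, fp, fn = _tp_fp_fn(cm)
    return float(2 * tp.sum() / (2 * tp.sum() + fp.sum() + fn.sum()))


@dataclass
class MetricReport:
    """Per-class and aggregate metrics for one model's prediction."""

    oa: float
    iou_per_class: np.ndarray
    f1_per_class: np.ndarray
    mean_iou: float
    mean_f1: float
    micro_f1: float
    class_names: tuple[str, ...] = field(default=DEFAULT_LEGEND.names)

    def to_dict(self) -> dict:
        def clean(x):
            return [None if np.isnan(v) else float(v) for v in x]
        return {
            "oa": self.oa,
            "mean_iou": self.mean_iou,
            "mean_f1": self.mean_f1,
            "micro_f1": self.micro_f1,
            "iou_per_class": clean(self.iou_per_class),
            "f1_per_class": clean(self.f1_per_class),
            "class_names": list(self.class_names),
        }


def evaluate(pred: LabelMask | np.ndarray, ref: LabelMask | np.ndarray,
             num_classes: int | None = None,
             class_names: tuple[str, ...] | None = None) -> MetricReport:
    """Confusion matrix plus the full metric set in one call."""
    cm = confusion_matrix(pred, ref, num_classes, class_names)
    iou, miou = per_class_iou(cm)
    f1, mf1 = per_class_f1(cm)
    names = cm.class_names if cm.class_names is not None else tuple(
        f"class {k}" for k in range(cm.num_classes)
    )
    return MetricReport(
        oa=overall_accuracy(cm),
        iou_per_class=iou,
        f1_per_class=f1,
        mean_iou=miou,
        mean_f1=mf1,
        micro_f1=micro_f1(cm),
        class_names=names,
    )


def hard_labels(probs: np.ndarray) -> np.ndarray:
    """Argmax class map from an (H, W, C) probability stack.

    np.argmax breaks ties toward the lowest class index, which is the
    documented deterministic rule. NaN (no-data) pixels raise.
    """
    probs = np.asarray(probs)
    if np.isnan(probs).any():
        raise ValueError("probability map contains no-data pixels")
    return probs.argmax(axis=-1).astype(np.uint8)


def write_report_table(path: str | Path, reports: dict[str, MetricReport]) -> None:
    """Emit a per-class IoU/F1 + OA table (models as columns) as CSV, and a
    JSON twin next to it."""
    path = Path(path)
    models = list(reports)
    names = reports[models[0]].class_names
    rows: list[list[str]] = [["Classes", "Metrics (%)", *models]]

    def pct(v: float) -> str:
        return "" if np.isnan(v) else f"{100 * v:.2f}"

    for k, cname in enumerate(names):
        rows.append([cname, "IoU", *[pct(reports[m].iou_per_class[k]) for m in models]])
        rows.append(["", "F1-score", *[pct(reports[m].f1_per_class[k]) for m in models]])
    rows.append(["All classes", "IoU", *[pct(reports[m].mean_iou) for m in models]])
    rows.append(["", "F1-score", *[pct(reports[m].mean_f1) for m in models]])
    rows.append(["", "OA", *[pct(reports[m].oa) for m in models]])
    with path.open("w", newline="") as fh:
        csv.writer(fh).writerows(rows)
    path.with_suffix(".json").write_text(
        json.dumps({m: r.to_dict() for m, r in reports.items()}, indent=2)
    )
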