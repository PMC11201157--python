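"""Per-class and aggregate segmentation evaluation.

All region metrics derive from a C-by-C pixel confusion matrix accumulated
over a dataset (rows = truth, columns = prediction): for class c,
TP = counts[c, c], FN = row_c - TP, FP = col_c - TP, TN = rest.

Two accuracy notions are reported side by side, because the classical
one-vs-rest accuracy (TP+TN)/(TP+TN+FP+FN) and the per-class accuracy
convention of segmentation toolboxes (recall, TP/(TP+FN)) disagree; the
aggregate MAcc uses the recall-style per-class accuracy, which is what the
study's tabulated values are consistent with.  GAcc is the pooled pixel
accuracy (trace/total).  MIoU and the per-class Dice follow the usual
Jaccard / F1 forms; Dice = 2*IoU/(1+IoU) identically.

The boundary F1 score (bfs) matches predicted and true class boundaries
within a Euclidean pixel tolerance theta (default 0.75% of the image
diagonal): boundary precision is the fraction of predicted boundary pixels
within theta of any true boundary pixel, boundary recall the converse, and
bfs their harmonic mean.  A pixel is a boundary pixel of class c if it has
the label c and any 4-neighbor (or the image border) differs.

Classes absent from both truth and prediction are *undefined*, excluded
from every mean — never silently counted as 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ConfusionAccumulator",
    "ClassMetrics",
    "MetricsReport",
    "accumulate",
    "class_metrics",
    "default_theta",
    "boundary_f1",
    "bfs_accumulate",
    "summarize",
]


@dataclass
class ConfusionAccumulator:
    """C x C pixel-count confusion matrix plus an image counter."""

    n_classes: int
    counts: np.ndarray = None  # type: ignore[assignment]
    n_images: int = 0

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros((self.n_classes, self.n_classes), dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.n_classes, self.n_classes):
            raise ValueError("counts must be C x C")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def merge(self, other: "ConfusionAccumulator") -> "ConfusionAccumulator":
        if other.n_classes != self.n_classes:
            raise ValueError("class-count mismatch")
        return ConfusionAccumulator(
            self.n_classes, self.counts + other.counts, self.n_images + other.n_images
        )


def accumulate(
    pred: np.ndarray, truth: np.ndarray, acc: ConfusionAccumulator
) -> ConfusionAccumulator:
    """Add one prediction/truth mask pair to the accumulator (in place)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    c = acc.n_classes
    if pred.min() < 0 or pred.max() >= c or truth.min() < 0 or truth.max() >= c:
        raise ValueError(f"labels outside [0, {c})")
    idx = truth.ravel().astype(np.int64) * c + pred.ravel().astype(np.int64)
    acc.counts += np.bincount(idx, minlength=c * c).reshape(c, c)
    acc.n_images += 1
    return acc


@dataclass(frozen=True)
class ClassMetrics:
    """One class's one-vs-rest metrics; None marks an undefined value."""

    acc_ovr: float | None
    class_acc: float | None  # recall-style accuracy
    iou: float | None
    dice: float | None
    precision: float | None
    recall: float | None
    support: int
    defined: bool


def class_metrics(acc: ConfusionAccumulator, c: int) -> ClassMetrics:
    """One-vs-rest metrics of class c from the confusion matrix."""
    if not 0 <= c < acc.n_classes:
        raise ValueError(f"class {c} outside [0, {acc.n_classes})")
    m = acc.counts
    tp = int(m[c, c])
    fn = int(m[c].sum()) - tp
    fp = int(m[:, c].sum()) - tp
    tn = acc.total - tp - fn - fp
    support = tp + fn
    if tp + fp + fn == 0:
        return ClassMetrics(None, None, None, None, None, None, support, False)

    def ratio(num, den):
        return num / den if den > 0 else None

    iou = tp / (tp + fp + fn)
    return ClassMetrics(
        acc_ovr=ratio(tp + tn, tp + tn + fp + fn),
        class_acc=ratio(tp, tp + fn),
        iou=iou,
        dice=2 * tp / (2 * tp + fp + fn),
        precision=ratio(tp, tp + fp),
        recall=ratio(tp, tp + fn),
        support=support,
        defined=True,
    )


# ---------------------------------------------------------------------------
# boundary F1
# ---------------------------------------------------------------------------


def default_theta(shape: tuple[int, int]) -> float:
    """Match tolerance: 0.75% of the image diagonal, in pixels."""
    h, w = shape
    return 0.0075 * float(np.hypot(h, w))


def _boundary(mask: np.ndarray, c: int) -> np.ndarray:
    """Pixels of class c with a differing 4-neighbor; border pixels count."""
    inside = mask == c
    if not inside.any():
        return inside
    padded = np.pad(inside, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    # image-edge pixels of the class are boundary by convention
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    return inside & ~interior


def boundary_f1(
    pred: np.ndarray, truth: np.ndarray, c: int, theta: float | None = None
) -> float | None:
    """Boundary F1 for class c on one mask pair; None if c absent from both."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if theta is None:
        theta = default_theta(pred.shape)
    if theta <= 0:
        raise ValueError("theta must be > 0")
    bp = _boundary(pred, c)
    bt = _boundary(truth, c)
    if not bp.any() and not bt.any():
        return None
    if not bp.any() or not bt.any():
        return 0.0
    # Euclidean distance from every pixel to the nearest boundary pixel
    d_to_truth = ndimage.distance_transform_edt(~bt)
    d_to_pred = ndimage.distance_transform_edt(~bp)
    precision = float((d_to_truth[bp] <= theta).mean())
    recall = float((d_to_pred[bt] <= theta).mean())
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def bfs_accumulate(
    pred: np.ndarray,
    truth: np.ndarray,
    n_classes: int,
    theta: float | None = None,
    store: list | None = None,
) -> list:
    """Append this image's per-class bfs (None where undefined) to ``store``."""
    if store is None:
        store = []
    store.append(
        [boundary_f1(pred, truth, c, theta) for c in range(n_classes)]
    )
    return store


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    per_class: pd.DataFrame
    gacc: float
    macc: float
    miou: float
    mbfs: float | None

    def to_csv(self, path: str | Path) -> None:
        """Per-class table with an aggregate footer row."""
        df = self.per_class.copy()
        footer = {col: np.nan for col in df.columns}
        footer.update(
            {"class": "AGGREGATE", "class_acc": self.macc, "iou": self.miou}
        )
        footer["acc_ovr"] = self.gacc  # GAcc in the accuracy column
        if self.mbfs is not None:
            footer["bfs"] = self.mbfs
        df = pd.concat([df, pd.DataFrame([footer])], ignore_index=True)
        df.to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "GAcc": self.gacc,
            "MAcc": self.macc,
            "MIoU": self.miou,
            "Mbfs": self.mbfs,
            "per_class": self.per_class.to_dict(orient="records"),
        }


def summarize(
    acc: ConfusionAccumulator,
    per_image_bfs: list | None = None,
    class_names: list[str] | None = None,
) -> MetricsReport:
    """Aggregate a confusion accumulator (plus optional per-image bfs rows).

    GAcc = trace/total; MAcc / MIoU are unweighted means over classes with
    defined metrics; each class's bfs is first averaged over the images
    where the class appears in either mask, then Mbfs averages over classes.
    """
    if acc.total == 0:
        raise ValueError("empty accumulator")
    c = acc.n_classes
    if class_names is None:
        class_names = [f"class_{i}" for i in range(c)]
    rows = []
    per_class_bfs: list[float | None] = [None] * c
    if per_image_bfs is not None:
        arr = [
            [row[k] for row in per_image_bfs if row[k] is not None] for k in range(c)
        ]
        per_class_bfs = [float(np.mean(v)) if v else None for v in arr]
    for k in range(c):
        cm = class_metrics(acc, k)
        rows.append(
            {
                "class": class_names[k],
                "support": cm.support,
                "acc_ovr": cm.acc_ovr,
                "class_acc": cm.class_acc,
                "iou": cm.iou,
                "dice": cm.dice,
                "precision": cm.precision,
                "recall": cm.recall,
                "bfs": per_class_bfs[k],
                "defined": cm.defined,
            }
        )
    df = pd.DataFrame(rows)
    defined = df[df["defined"]]
    bfs_vals = [v for v in per_class_bfs if v is not None]
    return MetricsReport(
        per_class=df,
        gacc=float(np.trace(acc.counts)) / acc.total,
        macc=float(defined["class_acc"].mean()),
        miou=float(defined["iou"].mean()),
        mbfs=float(np.mean(bfs_vals)) if bfs_vals else None,
    )
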