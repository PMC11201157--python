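"""Class-frequency statistics and loss weights for imbalanced datasets.

Algorithm-level class balancing: instead of resampling the data, each
pixel's loss contribution is multiplied by a per-class weight computed from
the pixel-frequency profile of the training partition.  Two weighting
schemes are provided besides uniform:

* ``inverse_frequency``: w_c = 1 / (C * f_c), so w_c * f_c is constant;
* ``median_frequency`` (default): w_c = median(f) / f_c, the standard
  median-frequency balancing of the encoder-decoder segmentation
  literature — dominant classes are down-weighted below 1, minority
  classes boosted above 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .mask_io import ClassTable, DatasetManifest, read_index_mask

__all__ = [
    "PixelFrequencyTable",
    "PresenceTable",
    "ClassWeights",
    "tally_dataset",
    "tally_masks",
    "presence_percentage",
    "compute_weights",
    "weighted_share_report",
]

SCHEMES = ("uniform", "inverse_frequency", "median_frequency")


@dataclass(frozen=True)
class PixelFrequencyTable:
    """Per-class pixel counts and shares over a dataset."""

    pixel_counts: np.ndarray  # (C,) int
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.pixel_counts)
        if (counts < 0).any():
            raise ValueError("pixel counts must be nonnegative")
        if counts.sum() == 0:
            raise ValueError("empty frequency table")

    @property
    def total_pixels(self) -> int:
        return int(np.sum(self.pixel_counts))

    @property
    def shares(self) -> np.ndarray:
        return np.asarray(self.pixel_counts, dtype=float) / self.total_pixels


@dataclass(frozen=True)
class PresenceTable:
    """Per-class image-presence counts (images with >= 1 pixel of the class)."""

    image_counts: np.ndarray  # (C,) int
    total_images: int
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.image_counts)
        if (counts < 0).any() or (counts > self.total_images).any():
            raise ValueError("image counts must lie in [0, total_images]")

    @property
    def presence_pcts(self) -> np.ndarray:
        return np.array(
            [
                presence_percentage(int(c), self.total_images)
                for c in self.image_counts
            ]
        )


@dataclass(frozen=True)
class ClassWeights:
    """Positive per-class loss multipliers."""

    weights: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)) or (w <= 0).any():
            raise ValueError("weights must be finite and > 0")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def __len__(self) -> int:
        return len(self.weights)


def tally_masks(masks, table: ClassTable) -> tuple[PixelFrequencyTable, PresenceTable]:
    """Tally an in-memory iterable of index masks."""
    c = len(table)
    pix = np.zeros(c, dtype=np.int64)
    pres = np.zeros(c, dtype=np.int64)
    n = 0
    for mask in masks:
        counts = np.bincount(np.asarray(mask).ravel(), minlength=c)
        if len(counts) > c:
            raise ValueError(f"mask contains labels outside the {c}-class table")
        pix += counts
        pres += counts > 0
        n += 1
    if n == 0:
        raise ValueError("no masks to tally")
    names = tuple(table.names)
    return (
        PixelFrequencyTable(pix, names),
        PresenceTable(pres, n, names),
    )


def tally_dataset(
    manifest: DatasetManifest, table: ClassTable
) -> tuple[PixelFrequencyTable, PresenceTable]:
    """Exact pixel and presence counts over all masks in a manifest."""
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    return tally_masks(
        (read_index_mask(r.mask_path, table) for r in manifest.records), table
    )


def presence_percentage(image_count: int, total: int) -> float:
    """100 * image_count / total, half-up rounded to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= image_count <= total:
        raise ValueError("image_count must lie in [0, total]")
    pct = Decimal(100 * image_count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def compute_weights(
    freq: PixelFrequencyTable, scheme: str = "median_frequency"
) -> ClassWeights:
    """Per-class weights from pixel shares.

    A class with zero pixels has no defined frequency weight; callers must
    exclude it from the table or smooth the counts explicitly first.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    f = freq.shares
    if scheme == "uniform":
        return ClassWeights(np.ones_like(f), scheme)
    if (f == 0).any():
        zero = [freq.names[i] for i in np.flatnonzero(f == 0)]
        raise ValueError(
            f"classes with zero pixels have no frequency weight: {zero}; "
            "exclude them from the table or smooth the counts explicitly"
        )
    if scheme == "inverse_frequency":
        return ClassWeights(1.0 / (len(f) * f), scheme)
    return ClassWeights(np.median(f) / f, scheme)


def weighted_share_report(
    freq: PixelFrequencyTable, weights: ClassWeights
) -> pd.DataFrame:
    """Raw vs weight-adjusted pixel shares, both as percentages.

    The adjusted column is w_c * f_c renormalized to sum to 100, showing how
    weighting deflates the dominant classes and inflates the minority ones.
    """
    if len(weights) != len(freq.names):
        raise ValueError(
            f"class-set mismatch: {len(freq.names)} classes vs {len(weights)} weights"
        )
    f = freq.shares
    w = np.asarray(weights.weights, dtype=float)
    wf = w * f
    return pd.DataFrame(
        {
            "class": list(freq.names),
            "pixel_share_pct": 100 * f,
            "weight": w,
            "weighted_share_pct": 100 * wf / wf.sum(),
        }
    )
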