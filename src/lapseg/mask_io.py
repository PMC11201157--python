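"""Image/mask I/O, color<->index mask conversion, resizing, and manifests.

Label masks come in two interchangeable forms: a *color mask* (8-bit RGB,
one color per class, for visualization) and an *index mask* (8-bit single
channel of class ids, for computation).  A :class:`ClassTable` binds the
two.  The bundled ``cholecseg13`` preset carries the thirteen surgical-scene
class names (background, tissues, instruments, blood, ...) of the
laparoscopic cholecystectomy dataset the method targets; its colors are a
palette chosen here for legibility, not a claim about the dataset's own
encoding.

Resizing treats images and masks differently on purpose: images are
interpolated bicubically (weighted average of the nearest 4x4 neighborhood)
while masks use nearest-neighbor, because interpolating class ids would
invent labels that exist in neither input class.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "ClassTable",
    "ManifestRecord",
    "DatasetManifest",
    "cholecseg13_table",
    "color_to_index",
    "index_to_color",
    "resize_pair",
    "split_manifest",
    "diff_overlay",
    "read_image",
    "write_image",
    "read_index_mask",
    "write_index_mask",
    "validate_mask",
]

PARTITIONS = ("train", "val", "test", "unassigned")


@dataclass(frozen=True)
class ClassTable:
    """Ordered class_id -> (name, RGB color) table."""

    entries: tuple[tuple[int, str, tuple[int, int, int]], ...]

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        names = [e[1] for e in self.entries]
        colors = [tuple(e[2]) for e in self.entries]
        if ids != list(range(len(ids))):
            raise ValueError("class ids must be consecutive from 0")
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        if len(set(colors)) != len(colors):
            raise ValueError("class colors must be unique")
        for c in colors:
            if len(c) != 3 or any(not (0 <= v <= 255) for v in c):
                raise ValueError(f"invalid RGB color {c}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e[1] for e in self.entries]

    @property
    def colors(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries], dtype=np.uint8)

    def id_of(self, name: str) -> int:
        for cid, n, _ in self.entries:
            if n == name:
                return cid
        raise KeyError(name)

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_rows(cls, rows) -> "ClassTable":
        entries = tuple(
            (int(r["id"]), str(r["name"]), (int(r["r"]), int(r["g"]), int(r["b"])))
            for r in sorted(rows, key=lambda r: int(r["id"]))
        )
        return cls(entries)

    @classmethod
    def read(cls, path: str | Path) -> "ClassTable":
        path = Path(path)
        if path.suffix == ".json":
            return cls.from_rows(json.loads(path.read_text()))
        with open(path, newline="") as fh:
            return cls.from_rows(csv.DictReader(fh))

    def write(self, path: str | Path) -> None:
        path = Path(path)
        rows = [
            {"id": cid, "name": name, "r": c[0], "g": c[1], "b": c[2]}
            for cid, name, c in self.entries
        ]
        if path.suffix == ".json":
            path.write_text(json.dumps(rows, indent=2))
            return
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["id", "name", "r", "g", "b"])
            w.writeheader()
            w.writerows(rows)


def cholecseg13_table() -> ClassTable:
    """The bundled 13-class surgical-scene preset."""
    ref = resources.files("lapseg.data").joinpath("cholecseg13.csv")
    with resources.as_file(ref) as p:
        return ClassTable.read(p)


@dataclass(frozen=True)
class ManifestRecord:
    image_path: str
    mask_path: str
    partition: str = "unassigned"

    def __post_init__(self) -> None:
        if self.partition not in PARTITIONS:
            raise ValueError(f"invalid partition {self.partition!r}")


@dataclass
class DatasetManifest:
    """Paired image/mask paths with train/val/test partition tags."""

    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        paths = [r.image_path for r in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("duplicate image paths in manifest")

    def __len__(self) -> int:
        return len(self.records)

    def partition(self, tag: str) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if r.partition == tag])

    @classmethod
    def read(cls, path: str | Path) -> "DatasetManifest":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls(
            [
                ManifestRecord(
                    r["image_path"], r["mask_path"], r.get("partition") or "unassigned"
                )
                for r in rows
            ]
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["image_path", "mask_path", "partition"])
            w.writeheader()
            for r in self.records:
                w.writerow(
                    {
                        "image_path": r.image_path,
                        "mask_path": r.mask_path,
                        "partition": r.partition,
                    }
                )


# ---------------------------------------------------------------------------
# pixel-level conversions
# ---------------------------------------------------------------------------


def validate_mask(mask: np.ndarray, table: ClassTable) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("index mask must be 2-D")
    if mask.size and (mask.min() < 0 or mask.max() >= len(table)):
        bad = int(mask.max() if mask.max() >= len(table) else mask.min())
        raise ValueError(f"label {bad} outside class table of size {len(table)}")
    return mask


def _pack(rgb: np.ndarray) -> np.ndarray:
    rgb = rgb.astype(np.int64)
    return (rgb[..., 0] << 16) | (rgb[..., 1] << 8) | rgb[..., 2]


def color_to_index(color_mask: np.ndarray, table: ClassTable) -> np.ndarray:
    """Map each pixel's exact RGB color to its class id.

    Matching is exact byte equality (masks are annotation artifacts, not
    photographs).  An unlisted color raises, naming the color and the first
    coordinate where it occurs.
    """
    cm = np.asarray(color_mask)
    if cm.ndim != 3 or cm.shape[2] != 3:
        raise ValueError("color mask must be HxWx3")
    keys = _pack(table.colors)
    packed = _pack(cm)
    lut = {int(k): i for i, k in enumerate(keys)}
    out = np.full(packed.shape, -1, dtype=np.int64)
    for k, i in lut.items():
        out[packed == k] = i
    if (out < 0).any():
        i, j = np.argwhere(out < 0)[0]
        raise ValueError(
            f"unknown color {tuple(int(v) for v in cm[i, j])} at pixel ({i}, {j})"
        )
    return out


def index_to_color(mask: np.ndarray, table: ClassTable) -> np.ndarray:
    """Render an index mask with its class colors (HxWx3 uint8)."""
    mask = validate_mask(mask, table)
    return table.colors[mask]


def resize_pair(
    image: np.ndarray, mask: np.ndarray, target: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Resize an image (bicubic) and its mask (nearest-neighbor) together.

    ``target`` is (H, W).  Nearest-neighbor on the mask guarantees the
    output label set is a subset of the input's.
    """
    th, tw = target
    if th <= 0 or tw <= 0:
        raise ValueError("target dimensions must be positive")
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] == (th, tw):
        return image.copy(), mask.copy()
    im = Image.fromarray(image.astype(np.uint8)).resize((tw, th), Image.BICUBIC)
    mk = Image.fromarray(mask.astype(np.uint8)).resize((tw, th), Image.NEAREST)
    return np.asarray(im), np.asarray(mk).astype(mask.dtype)


def split_manifest(
    manifest: DatasetManifest,
    fractions: tuple[float, float, float],
    seed: int,
) -> DatasetManifest:
    """Assign train/val/test tags: |val| = floor(f_val*N), |test| =
    floor(f_test*N), remainder to train.

    Records are canonically sorted by image path before the seeded shuffle,
    so the assignment is independent of filesystem ordering.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.min() < 0 or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be nonnegative and sum to 1")
    recs = sorted(manifest.records, key=lambda r: r.image_path)
    n = len(recs)
    order = np.random.default_rng(seed).permutation(n)
    n_val = int(np.floor(fr[1] * n))
    n_test = int(np.floor(fr[2] * n))
    n_train = n - n_val - n_test
    tags = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    out: list[ManifestRecord | None] = [None] * n
    for pos, tag in zip(order, tags):
        r = recs[pos]
        out[pos] = ManifestRecord(r.image_path, r.mask_path, tag)
    return DatasetManifest([r for r in out if r is not None])


def diff_overlay(pred: np.ndarray, truth: np.ndarray, table: ClassTable) -> np.ndarray:
    """Channel-split disagreement overlay of two masks.

    Each mask is rendered to grayscale (class id scaled by 255/(C-1)); the
    output image takes R from the prediction and G = B from the truth, so
    agreeing pixels come out gray while disagreements show as magenta
    (prediction-only intensity) or green (truth-only).
    """
    pred = validate_mask(pred, table)
    truth = validate_mask(truth, table)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    c = len(table)
    scale = 255.0 / max(c - 1, 1)
    pg = np.round(pred * scale).astype(np.uint8)
    tg = np.round(truth * scale).astype(np.uint8)
    return np.stack([pg, tg, tg], axis=-1)


# ---------------------------------------------------------------------------
# PNG I/O
# ---------------------------------------------------------------------------


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(image: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_index_mask(path: str | Path, table: ClassTable | None = None) -> np.ndarray:
    mask = np.asarray(Image.open(path)).astype(np.int64)
    if mask.ndim != 2:
        raise ValueError(f"{path}: index masks must be single-channel PNG")
    if table is not None:
        try:
            validate_mask(mask, table)
        except ValueError as e:
            raise ValueError(f"{path}: {e}") from e
    return mask


def write_index_mask(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask)
    if mask.max(initial=0) > 255:
        raise ValueError("index masks above 255 classes are not supported")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(mask.astype(np.uint8), mode="L").save(path)
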