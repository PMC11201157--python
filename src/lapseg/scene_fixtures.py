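"""Synthetic imbalanced surgical-scene fixtures.

Generates paired RGB images and index masks whose *statistics* mimic the
laparoscopic cholecystectomy dataset the segmentation method targets:
thirteen classes, per-class image-presence frequencies spanning 3% to 100%,
and a pixel-share profile with four dominant classes (~27/22/21/15% of all
pixels) and four minority structures below 1%.  No anatomical realism is
claimed: classes are stylized shape families (blobs for tissues, thin
curves for ducts/vessels/ligaments, edge-entering elongated tools for
instruments, scattered specks for blood) over a noisy, blurred, unevenly
lit color rendering.

Every sample is deterministic given ``(config.seed, index)`` via a
counter-style sub-seed, so datasets regenerate bit-identically and samples
are order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .mask_io import ClassTable, DatasetManifest, ManifestRecord, write_image, write_index_mask

__all__ = [
    "ClassSpec",
    "SceneConfig",
    "SceneSample",
    "cholecseg_profile",
    "generate_scene",
    "generate_dataset",
]

SHAPE_FAMILIES = (
    "background",
    "large_blob",
    "medium_blob",
    "thin_curve",
    "elongated_tool",
    "scattered_specks",
)

# Painting proceeds back-to-front so that instruments occlude tissue, as in
# a real laparoscopic scene.
PAINT_ORDER = ("large_blob", "medium_blob", "thin_curve", "scattered_specks", "elongated_tool")

# Largest area a single structure of each family may occupy when present,
# as a fraction of the image.  Rare thin structures are capped well below
# target_share / presence_prob so that they stay small *and* rare.
AREA_CAP = {
    "large_blob": 0.45,
    "medium_blob": 0.25,
    "thin_curve": 0.05,
    "elongated_tool": 0.15,
    "scattered_specks": 0.05,
}


@dataclass(frozen=True)
class ClassSpec:
    name: str
    presence_prob: float
    target_pixel_share: float
    shape_family: str
    base_color: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValueError(f"{self.name}: presence_prob outside [0, 1]")
        if not 0.0 <= self.target_pixel_share <= 1.0:
            raise ValueError(f"{self.name}: target_pixel_share outside [0, 1]")
        if self.shape_family not in SHAPE_FAMILIES:
            raise ValueError(f"{self.name}: unknown shape family {self.shape_family!r}")


@dataclass(frozen=True)
class SceneConfig:
    """Full recipe for one synthetic dataset."""

    class_specs: tuple[ClassSpec, ...]
    image_size: tuple[int, int] = (96, 96)
    noise_sd: float = 10.0
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_specs) < 2:
            raise ValueError("need at least background plus one class")
        bg = [s for s in self.class_specs if s.shape_family == "background"]
        if len(bg) != 1:
            raise ValueError("exactly one class must use the background family")
        if self.class_specs[0].shape_family != "background":
            raise ValueError("class 0 must be the background")
        if bg[0].presence_prob != 1.0:
            raise ValueError("background presence_prob must be 1")
        fg_share = sum(s.target_pixel_share for s in self.class_specs[1:])
        if fg_share > 1.0 + 1e-9:
            raise ValueError("foreground pixel-share targets exceed 1")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")

    @property
    def n_classes(self) -> int:
        return len(self.class_specs)

    def class_table(self) -> ClassTable:
        return ClassTable(
            tuple(
                (i, s.name, tuple(s.base_color))
                for i, s in enumerate(self.class_specs)
            )
        )

    def conditional_area(self, class_id: int) -> float:
        """Fraction of the image a structure occupies *when present*."""
        s = self.class_specs[class_id]
        if s.shape_family == "background":
            return 1.0
        if s.presence_prob == 0.0:
            return 0.0
        return min(s.target_pixel_share / s.presence_prob, AREA_CAP[s.shape_family])

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "image_size": list(self.image_size),
            "noise_sd": self.noise_sd,
            "blur_sigma": self.blur_sigma,
            "seed": self.seed,
            "class_specs": [
                {
                    "name": s.name,
                    "presence_prob": s.presence_prob,
                    "target_pixel_share": s.target_pixel_share,
                    "shape_family": s.shape_family,
                    "base_color": list(s.base_color),
                }
                for s in self.class_specs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        return cls(
            class_specs=tuple(
                ClassSpec(
                    s["name"],
                    s["presence_prob"],
                    s["target_pixel_share"],
                    s["shape_family"],
                    tuple(s["base_color"]),
                )
                for s in d["class_specs"]
            ),
            image_size=tuple(d["image_size"]),
            noise_sd=d["noise_sd"],
            blur_sigma=d["blur_sigma"],
            seed=d["seed"],
        )


@dataclass(frozen=True)
class SceneSample:
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) int


# (name, presence, pixel share, family, color): presence frequencies follow
# the per-image class distribution of the real dataset; dominant shares are
# ~27/22/21/15% and the four minority structures stay below 1% of pixels.
_CHOLECSEG13 = [
    ("Black Background", 1.0, 0.27, "background", (0, 0, 0)),
    ("Abdominal Wall", 0.8979, 0.22, "large_blob", (210, 125, 130)),
    ("Liver", 1.0, 0.21, "large_blob", (120, 30, 30)),
    ("Gastrointestinal Tract", 0.5641, 0.03, "medium_blob", (230, 170, 170)),
    ("Fat", 0.9295, 0.15, "large_blob", (230, 210, 100)),
    ("Grasper", 0.7450, 0.015, "elongated_tool", (170, 170, 180)),
    ("Connective Tissue", 0.1980, 0.02, "medium_blob", (200, 180, 160)),
    ("Blood", 0.0856, 0.008, "scattered_specks", (180, 20, 40)),
    ("Cystic Duct", 0.0307, 0.003, "thin_curve", (120, 200, 140)),
    ("L-hook Electrocautery", 0.2790, 0.012, "elongated_tool", (100, 120, 180)),
    ("Gallbladder", 0.8491, 0.045, "medium_blob", (110, 160, 70)),
    ("Hepatic Vein", 0.0392, 0.004, "thin_curve", (60, 60, 140)),
    ("Liver Ligament", 0.0297, 0.003, "thin_curve", (220, 150, 90)),
]


def cholecseg_profile(
    n_classes: int = 13,
    image_size: tuple[int, int] = (96, 96),
    seed: int = 0,
) -> SceneConfig:
    """The 13-class imbalanced preset.

    Dominant pixel-share targets 0.27/0.22/0.21/0.15 (background, abdominal
    wall, liver, fat); blood, cystic duct, hepatic vein, and liver ligament
    each below 1%; presence probabilities follow the per-image frequencies
    of the real dataset (liver in every image, cystic duct in ~3%).
    """
    if n_classes != 13:
        raise ValueError("the cholecseg preset is defined for exactly 13 classes")
    return SceneConfig(
        class_specs=tuple(ClassSpec(*row) for row in _CHOLECSEG13),
        image_size=image_size,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# shape painting
# ---------------------------------------------------------------------------


def _grid(h, w):
    return np.mgrid[0:h, 0:w]


def _paint_ellipse(mask, cid, cy, cx, a, b, angle, yy, xx):
    ca, sa = np.cos(angle), np.sin(angle)
    y, x = yy - cy, xx - cx
    u = ca * x + sa * y
    v = -sa * x + ca * y
    mask[(u / max(a, 1e-6)) ** 2 + (v / max(b, 1e-6)) ** 2 <= 1.0] = cid


def _paint_blob(mask, cid, area_px, rng, yy, xx, n_ellipses, anchor=None,
                tile_only=False):
    """Union of overlapping ellipses, grown until the claimed pixel count
    reaches the requested area (border clipping and overlap are measured,
    not estimated).

    With ``tile_only`` the blob claims pixels still labeled background, so
    the dominant tissue planes tile the scene rather than burying each
    other; medium structures (e.g. a gallbladder resting on the liver) and
    the thin structures and instruments painted later overwrite freely."""
    h, w = mask.shape
    if anchor is None:
        cy0 = rng.uniform(0.25 * h, 0.75 * h)
        cx0 = rng.uniform(0.25 * w, 0.75 * w)
    else:
        cy0, cx0 = anchor
    k_min, k_max = n_ellipses
    free = (mask == 0) if tile_only else np.ones(mask.shape, dtype=bool)
    layer = np.zeros(mask.shape, dtype=bool)
    first = rng.uniform(0.55, 0.8) if k_max > 1 else 1.0
    # tiled blobs compete for free space and need more growth attempts
    for i in range(16 if tile_only else 10):
        painted = int((layer & free).sum())
        remaining = area_px - painted
        if i >= k_min and remaining <= 0.02 * area_px:
            break
        if i == 0:
            target = max(first * area_px, 4.0)
            cy, cx = cy0, cx0
        else:
            # grow from a random already-painted pixel so the new ellipse
            # extends the union instead of hiding inside it
            target = max(remaining * 1.3, 9.0)
            pts = np.argwhere(layer & free)
            if len(pts) == 0:
                pts = np.argwhere(layer)
            if len(pts) == 0:
                break
            py, px = pts[rng.integers(len(pts))]
            jit = 0.2 * np.sqrt(max(remaining, 1.0))
            cy = np.clip(py + rng.normal(0, jit), 0, h - 1)
            cx = np.clip(px + rng.normal(0, jit), 0, w - 1)
        ratio = rng.uniform(1.2, 2.5)  # semi-axis aspect
        b = np.sqrt(target / (np.pi * ratio))
        a = ratio * b
        sub = np.zeros(mask.shape, dtype=bool)
        _paint_ellipse(sub, True, cy, cx, a, b, rng.uniform(0, np.pi), yy, xx)
        layer |= sub
    mask[layer & free] = cid


def _paint_curve(mask, cid, area_px, rng, yy, xx):
    """One or more dilated quadratic Bezier strokes totalling ~area_px."""
    h, w = mask.shape
    for _ in range(4):
        painted = int((mask == cid).sum())
        if painted >= 0.9 * area_px:
            break
        _paint_curve_once(mask, cid, area_px - painted, rng, yy, xx)


def _paint_curve_once(mask, cid, area_px, rng, yy, xx):
    h, w = mask.shape
    width = int(rng.integers(1, 4))
    eff_width = 2 * width - 1  # dilation by (width-1) from a 1-px stroke
    length = min(area_px / eff_width, 1.5 * (h + w))
    p0 = rng.uniform([0.15 * h, 0.15 * w], [0.85 * h, 0.85 * w])
    # aim roughly through the interior so most of the arc stays on-image
    angle = np.arctan2(h / 2 - p0[0], w / 2 - p0[1]) + rng.normal(0, 0.7)
    p2 = p0 + length * np.array([np.sin(angle), np.cos(angle)])
    p1 = 0.5 * (p0 + p2) + rng.normal(0, 0.1 * length, 2)
    t = np.linspace(0, 1, max(int(4 * length), 16))[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    pts = np.round(pts).astype(int)
    keep = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    pts = pts[keep]
    if len(pts) == 0:
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        _paint_ellipse(mask, cid, cy, cx, 2, 1, 0.0, yy, xx)
        return
    stroke = np.zeros(mask.shape, dtype=bool)
    stroke[pts[:, 0], pts[:, 1]] = True
    if width > 1:
        stroke = ndimage.binary_dilation(stroke, iterations=width - 1)
    mask[stroke] = cid


def _paint_specks(mask, cid, area_px, rng, yy, xx):
    h, w = mask.shape
    k = int(rng.integers(3, 11))
    raw = rng.uniform(0.5, 1.5, k)
    areas = raw / raw.sum() * area_px
    for a_px in areas:
        r = max(np.sqrt(a_px / np.pi), 1.0)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        _paint_ellipse(mask, cid, cy, cx, r, r, 0.0, yy, xx)


def _paint_tool(mask, cid, area_px, rng, yy, xx):
    """Rotated rectangle plus triangular tip entering from an image edge."""
    h, w = mask.shape
    aspect = rng.uniform(4.0, 8.0)
    wd = max(np.sqrt(area_px / aspect), 2.0)
    length = area_px / wd
    edge = rng.integers(0, 4)
    if edge == 0:
        ey, ex = 0.0, rng.uniform(0, w)
    elif edge == 1:
        ey, ex = float(h - 1), rng.uniform(0, w)
    elif edge == 2:
        ey, ex = rng.uniform(0, h), 0.0
    else:
        ey, ex = rng.uniform(0, h), float(w - 1)
    # aim toward the interior with some wobble
    to_c = np.arctan2(h / 2 - ey, w / 2 - ex) + rng.normal(0, 0.3)
    dy, dx = np.sin(to_c), np.cos(to_c)
    u = (yy - ey) * dy + (xx - ex) * dx  # along-axis distance
    v = -(yy - ey) * dx + (xx - ex) * dy  # perpendicular
    shaft = (u >= 0) & (u <= length) & (np.abs(v) <= wd / 2)
    tip_len = 1.5 * wd
    with np.errstate(divide="ignore", invalid="ignore"):
        taper = (wd / 2) * (1.0 - (u - length) / tip_len)
    tip = (u > length) & (u <= length + tip_len) & (np.abs(v) <= taper)
    mask[shaft | tip] = cid


def generate_scene(config: SceneConfig, index: int) -> SceneSample:
    """Render sample ``index``: deterministic given (config.seed, index)."""
    h, w = config.image_size
    rng = np.random.default_rng([config.seed, int(index)])
    yy, xx = _grid(h, w)
    mask = np.zeros((h, w), dtype=np.int64)
    total = h * w

    # presence draws in class-id order, so they are stable across families
    present = {
        cid: (spec.presence_prob >= 1.0 or rng.random() < spec.presence_prob)
        for cid, spec in enumerate(config.class_specs)
    }

    # home anchors keep the dominant blobs mostly disjoint (rough anatomy:
    # distinct tissue planes), limiting occlusion of one tissue by another
    large_ids = [
        cid
        for cid, s in enumerate(config.class_specs)
        if s.shape_family == "large_blob"
    ]
    anchors = {}
    for rank, cid in enumerate(large_ids):
        band = (rank + 0.5) / max(len(large_ids), 1)
        anchors[cid] = (
            np.clip(band * h + rng.normal(0, 0.06 * h), 0.1 * h, 0.9 * h),
            rng.uniform(0.3 * w, 0.7 * w),
        )

    # tissue blobs are later occluded by curves/specks/tools; inflate their
    # requested area by the expected top-layer coverage (plus the 2% growth
    # stop tolerance) so realized shares land on target
    def _coverage(families):
        return sum(
            s.presence_prob * config.conditional_area(cid)
            for cid, s in enumerate(config.class_specs)
            if s.shape_family in families
        )

    top_share = _coverage(("thin_curve", "scattered_specks", "elongated_tool"))
    mid_share = _coverage(("medium_blob",))
    large_inflate = 1.02 / max(1.0 - top_share - mid_share, 0.5)
    mid_inflate = 1.02 / max(1.0 - top_share, 0.5)

    for family in PAINT_ORDER:
        for cid, spec in enumerate(config.class_specs):
            if spec.shape_family != family or not present[cid]:
                continue
            area_px = config.conditional_area(cid) * total
            if family == "large_blob":
                area_px *= large_inflate
            elif family == "medium_blob":
                area_px *= mid_inflate
            if area_px < 1:
                continue
            if family == "large_blob":
                _paint_blob(mask, cid, area_px, rng, yy, xx, (2, 4), anchors[cid],
                            tile_only=True)
            elif family == "medium_blob":
                _paint_blob(mask, cid, area_px, rng, yy, xx, (1, 2))
            elif family == "thin_curve":
                _paint_curve(mask, cid, area_px, rng, yy, xx)
            elif family == "scattered_specks":
                _paint_specks(mask, cid, area_px, rng, yy, xx)
            else:
                _paint_tool(mask, cid, area_px, rng, yy, xx)

    # guarantee at least one pixel for classes whose presence draw succeeded
    for cid, spec in enumerate(config.class_specs[1:], start=1):
        if present[cid] and not (mask == cid).any():
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            mask[cy, cx] = cid

    colors = np.array([s.base_color for s in config.class_specs], dtype=float)
    img = colors[mask]
    # smooth illumination gradient: a random tilted plane
    gy, gx = rng.normal(0, 1, 2)
    plane = (gy * (yy / h - 0.5) + gx * (xx / w - 0.5)) * rng.uniform(10, 30)
    img = img + plane[..., None]
    img = img + rng.normal(0.0, config.noise_sd, img.shape)
    if config.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, (config.blur_sigma, config.blur_sigma, 0))
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SceneSample(image=img, mask=mask)


def generate_dataset(config: SceneConfig, n: int, out_dir: str | Path) -> DatasetManifest:
    """Write ``n`` PNG pairs, a manifest CSV, and a config sidecar."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for i in range(n):
        sample = generate_scene(config, i)
        ip = out / f"img_{i:05d}.png"
        mp = out / f"mask_{i:05d}.png"
        write_image(sample.image, ip)
        write_index_mask(sample.mask, mp)
        records.append(ManifestRecord(str(ip), str(mp)))
    manifest = DatasetManifest(records)
    manifest.write(out / "manifest.csv")
    (out / "scene_config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return manifest
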