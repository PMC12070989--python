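"""Synthetic lesion image/mask generation, polygon rasterization and paired augmentation.

Images are 2D float arrays with intensities in [0, 1]; masks are 2D integer
arrays where 0 is background and k > 0 labels the k-th region.  Class-conditioned
profiles drive a generator whose regions differ in size, count, shape and
texture so that every downstream stage can be exercised without real data.
"""

from __future__ import annotations

import json

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence  # noqa: F401

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .errors import AnnotationError, CoordinateError, GenerationError, PairingError

DEFAULT_CANVAS = (128, 128)

__all__ = [
    "PolygonAnnotation",
    "ClassProfile",
    "DEFAULT_PROFILES",
    "DEFAULT_CANVAS",
    "rasterize_polygons",
    "read_labelme",
    "generate_synthetic_case",
    "augment_pair",
    "sample_augment_ops",
    "generate_dataset",
    "validate_image",
    "validate_mask",
    "save_image_png",
    "load_image_png",
    "save_mask_png",
    "load_mask_png",
]


# ---------------------------------------------------------------------------
# validation helpers


def validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise PairingError(f"image must be 2D, got shape {image.shape}")
    if image.shape[0] < 8 or image.shape[1] < 8:
        raise PairingError(f"image must be at least 8x8, got {image.shape}")
    if not np.isfinite(image).all() or image.min() < 0 or image.max() > 1:
        raise PairingError("image intensities must be finite and in [0, 1]")
    return image


def validate_mask(mask: np.ndarray, image: np.ndarray | None = None) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise PairingError(f"mask must be 2D, got shape {mask.shape}")
    if not np.issubdtype(mask.dtype, np.integer):
        raise PairingError(f"mask must be integer-valued, got dtype {mask.dtype}")
    if mask.min() < 0:
        raise PairingError("mask labels must be non-negative")
    if image is not None and mask.shape != image.shape:
        raise PairingError(f"mask shape {mask.shape} != image shape {image.shape}")
    return mask


# ---------------------------------------------------------------------------
# annotations


@dataclass(frozen=True)
class PolygonAnnotation:
    """A closed polygon in pixel coordinates (x = column, y = row)."""

    vertices: tuple[tuple[float, float], ...]
    class_name: str = ""

    def __post_init__(self):
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise AnnotationError(f"polygon needs >=3 vertices, got {len(verts)}")
        v = np.asarray(verts)
        d = v - v[0]
        # all-collinear check: every vertex on the line through v0 with direction v1-v0
        base = v[1] - v[0]
        crosses = d[:, 0] * base[1] - d[:, 1] * base[0]
        if np.allclose(crosses, 0.0):
            raise AnnotationError("polygon vertices are collinear")


def read_labelme(source) -> list[PolygonAnnotation]:
    """Parse a LabelMe-style JSON document (path, file object or dict)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = json.load(fh)
    elif isinstance(source, dict):
        doc = source
    else:
        doc = json.load(source)
    shapes = doc.get("shapes")
    if shapes is None:
        raise AnnotationError("LabelMe document lacks a 'shapes' list")
    out = []
    for shape in shapes:
        pts = tuple((float(p[0]), float(p[1])) for p in shape["points"])
        out.append(PolygonAnnotation(vertices=pts, class_name=str(shape.get("label", ""))))
    return out


def _point_in_polygon(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Vectorized even-odd test with boundary inclusion for pixel centers."""
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        # even-odd ray cast toward +x
        cond = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = (x2 - x1) * (py - y1) / (y2 - y1) + x1
        inside ^= cond & (px < xint)
        # boundary: point on the closed segment
        ex, ey = x2 - x1, y2 - y1
        seg2 = ex * ex + ey * ey
        if seg2 == 0:
            on_edge |= (np.abs(px - x1) < 1e-9) & (np.abs(py - y1) < 1e-9)
            continue
        t = ((px - x1) * ex + (py - y1) * ey) / seg2
        t = np.clip(t, 0.0, 1.0)
        dist2 = (x1 + t * ex - px) ** 2 + (y1 + t * ey - py) ** 2
        on_edge |= dist2 < 1e-18
    return inside | on_edge


def rasterize_polygons(
    annotations: Sequence[PolygonAnnotation], image_size: tuple[int, int]
) -> np.ndarray:
    """Fill polygons onto a blank mask; the k-th annotation gets label k (1-based).

    A pixel belongs to a polygon iff its center is inside under the even-odd
    rule or exactly on the boundary.  Later annotations overwrite earlier ones.
    """
    h, w = int(image_size[0]), int(image_size[1])
    if h <= 0 or w <= 0:
        raise CoordinateError(f"image_size must be positive, got {image_size}")
    mask = np.zeros((h, w), dtype=np.int32)
    if not annotations:
        return mask
    yy, xx = np.mgrid[0:h, 0:w]
    px, py = xx.astype(float), yy.astype(float)
    for k, ann in enumerate(annotations, start=1):
        verts = np.asarray(ann.vertices, dtype=float)
        if (verts[:, 0] < 0).any() or (verts[:, 0] > w - 1).any() or (
            verts[:, 1] < 0
        ).any() or (verts[:, 1] > h - 1).any():
            raise CoordinateError(
                f"annotation {k}: vertex outside [0,{w - 1}]x[0,{h - 1}]"
            )
        mask[_point_in_polygon(px, py, verts)] = k
    return mask


# ---------------------------------------------------------------------------
# class-conditioned generation

CLASS_NAMES = ("normal", "CIN1", "CIN2", "CIN3", "carcinoma")


@dataclass(frozen=True)
class ClassProfile:
    """Generator parameters for one lesion class.

    ``contrast_level`` in [0, 1] scales the in-region texture noise so that
    expected GLCM contrast increases monotonically with it.  ``circularity_target``
    in (0, 1] shapes regions from elongated (low) to circular (1).
    """

    class_name: str
    area_range: tuple[int, int]
    n_regions_range: tuple[int, int]
    contrast_level: float
    circularity_target: float
    intensity_mean: float
    canvas: tuple[int, int] = DEFAULT_CANVAS

    def __post_init__(self):
        lo, hi = self.area_range
        if not (0 < lo <= hi):
            raise GenerationError(f"area_range must be positive and ordered: {self.area_range}")
        nlo, nhi = self.n_regions_range
        if not (0 < nlo <= nhi):
            raise GenerationError(
                f"n_regions_range must be positive and ordered: {self.n_regions_range}"
            )
        if not 0 < self.circularity_target <= 1:
            raise GenerationError("circularity_target must be in (0, 1]")
        if not 0 < self.intensity_mean < 1:
            raise GenerationError("intensity_mean must be in (0, 1)")
        if self.contrast_level < 0:
            raise GenerationError("contrast_level must be >= 0")


#: Five mutually distinct profiles following the qualitative trend of rising
#: texture contrast and falling circularity with lesion severity.
DEFAULT_PROFILES = (
    ClassProfile("normal", (350, 500), (1, 3), 0.15, 0.90, 0.65),
    ClassProfile("CIN1", (150, 260), (2, 4), 0.35, 0.80, 0.68),
    ClassProfile("CIN2", (220, 340), (3, 5), 0.55, 0.65, 0.55),
    ClassProfile("CIN3", (280, 420), (4, 6), 0.75, 0.55, 0.58),
    ClassProfile("carcinoma", (330, 520), (5, 8), 0.95, 0.40, 0.50),
)

_BACKGROUND_MEAN = 0.25
_BACKGROUND_STD = 0.02
_NOISE_BASE = 0.02
_NOISE_SPAN = 0.28


def _place_region(
    occupancy: np.ndarray, profile: ClassProfile, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray] | None:
    """Try to place one ellipse-shaped region; returns (rows, cols) or None."""
    h, w = occupancy.shape
    lo, hi = profile.area_range
    target = rng.uniform(lo, hi)
    aspect = 1.0 / max(profile.circularity_target, 0.2)
    b = np.sqrt(target / (np.pi * aspect))  # semi-minor
    a = aspect * b  # semi-major
    theta = rng.uniform(0, np.pi)
    # forbid placement touching existing regions (keep components separated)
    blocked = ndimage.binary_dilation(occupancy, iterations=2)
    for _ in range(40):
        margin = int(np.ceil(a)) + 2
        if 2 * margin >= min(h, w):
            return None
        r0 = rng.integers(margin, h - margin)
        c0 = rng.integers(margin, w - margin)
        rr, cc = draw_ellipse(r0, c0, a, b, shape=(h, w), rotation=theta)
        if rr.size == 0:
            continue
        area = rr.size
        if not (lo <= area <= hi):
            # rescale radii toward the target pixel count and re-rasterize
            scale = np.sqrt(target / max(area, 1))
            rr, cc = draw_ellipse(r0, c0, a * scale, b * scale, shape=(h, w), rotation=theta)
            area = rr.size
            if not (lo <= area <= hi):
                continue
        if blocked[rr, cc].any():
            continue
        return rr, cc
    return None


def generate_synthetic_case(
    profile: ClassProfile, rng_seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministically generate one (image, mask) pair for a class profile."""
    rng = np.random.default_rng(rng_seed)
    h, w = profile.canvas
    nlo, nhi = profile.n_regions_range
    n = int(rng.integers(nlo, nhi + 1))
    mask = np.zeros((h, w), dtype=np.int32)
    occupancy = np.zeros((h, w), dtype=bool)
    for k in range(1, n + 1):
        placed = None
        for _ in range(25):
            placed = _place_region(occupancy, profile, rng)
            if placed is not None:
                break
        if placed is None:
            raise GenerationError(
                f"cannot fit {n} regions of profile {profile.class_name!r} "
                f"on a {h}x{w} canvas"
            )
        rr, cc = placed
        mask[rr, cc] = k
        occupancy[rr, cc] = True

    image = rng.normal(_BACKGROUND_MEAN, _BACKGROUND_STD, size=(h, w))
    sigma = _NOISE_BASE + _NOISE_SPAN * profile.contrast_level
    fg = mask > 0
    image[fg] = profile.intensity_mean + rng.normal(0.0, sigma, size=int(fg.sum()))
    return np.clip(image, 0.0, 1.0), mask


# ---------------------------------------------------------------------------
# paired augmentation

AugmentOp = tuple[str, float | int | None]


def sample_augment_ops(rng: np.random.Generator) -> list[AugmentOp]:
    """Draw a random augmentation recipe: rotation/flips + photometric jitter + scale."""
    ops: list[AugmentOp] = []
    k = int(rng.integers(0, 4))
    if k:
        ops.append(("rot90", k))
    if rng.random() < 0.5:
        ops.append(("hflip", None))
    if rng.random() < 0.5:
        ops.append(("vflip", None))
    ops.append(("brightness", float(rng.uniform(-0.08, 0.08))))
    ops.append(("contrast", float(rng.uniform(0.9, 1.1))))
    if rng.random() < 0.5:
        ops.append(("scale", float(rng.uniform(0.9, 1.1))))
    return ops


def _rescale_pair(image, mask, factor):
    """Zoom both arrays (bilinear/nearest) and center-crop/pad back to shape."""
    h, w = image.shape
    zi = ndimage.zoom(image, factor, order=1)
    zm = ndimage.zoom(mask, factor, order=0)
    out_i = np.zeros((h, w), dtype=image.dtype)
    out_m = np.zeros((h, w), dtype=mask.dtype)
    zh, zw = zi.shape
    # source and destination windows for a centered crop/pad
    sh, dh = max(0, (zh - h) // 2), max(0, (h - zh) // 2)
    sw, dw = max(0, (zw - w) // 2), max(0, (w - zw) // 2)
    ch, cw = min(h, zh), min(w, zw)
    out_i[dh : dh + ch, dw : dw + cw] = zi[sh : sh + ch, sw : sw + cw]
    out_m[dh : dh + ch, dw : dw + cw] = zm[sh : sh + ch, sw : sw + cw]
    return out_i, out_m


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    ops: Iterable[AugmentOp],
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the same geometric ops to image and mask; photometric ops to the image only.

    Masks move through geometric transforms with nearest-neighbor label
    preservation; the image is clipped back to [0, 1] after intensity changes.
    """
    image = validate_image(image)
    mask = validate_mask(mask, image)
    img = image.copy()
    msk = mask.copy()
    for name, value in ops:
        if name == "rot90":
            k = int(value) if value is not None else 1
            img = np.rot90(img, k)
            msk = np.rot90(msk, k)
        elif name == "hflip":
            img = img[:, ::-1]
            msk = msk[:, ::-1]
        elif name == "vflip":
            img = img[::-1, :]
            msk = msk[::-1, :]
        elif name == "brightness":
            img = np.clip(img + float(value), 0.0, 1.0)
        elif name == "contrast":
            img = np.clip((img - 0.5) * float(value) + 0.5, 0.0, 1.0)
        elif name == "scale":
            img, msk = _rescale_pair(img, msk, float(value))
            img = np.clip(img, 0.0, 1.0)
        else:
            raise ValueError(f"unknown augmentation op {name!r}")
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


# ---------------------------------------------------------------------------
# PNG I/O (8-bit images, 16-bit label masks)


def save_image_png(path, image: np.ndarray) -> None:
    arr = np.round(validate_image(image) * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def load_image_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"), dtype=float)
    return arr / 255.0


def save_mask_png(path, mask: np.ndarray) -> None:
    mask = validate_mask(mask)
    if mask.max() > 65535:
        raise PairingError("mask labels exceed 16-bit range")
    Image.fromarray(mask.astype(np.uint16)).save(path, format="PNG")


def load_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.int32)


# ---------------------------------------------------------------------------
# dataset generation


def _case_seed(rng_seed: int, class_idx: int, item: int) -> int:
    ss = np.random.SeedSequence((int(rng_seed), int(class_idx), int(item)))
    return int(ss.generate_state(1)[0])


def generate_dataset(
    profiles: Sequence[ClassProfile],
    n_per_class: int,
    rng_seed: int,
    out_dir,
    augment: bool = True,
) -> pd.DataFrame:
    """Write ``n_per_class`` augmented image+mask pairs per class plus a manifest.

    Layout: ``<out>/<class>/images/<class>_<i>.png`` (8-bit grayscale) and
    ``<out>/<class>/masks/<class>_<i>.png`` (16-bit labels), with
    ``<out>/manifest.csv`` (columns class, image_path, mask_path, seed).
    """
    if n_per_class < 1:
        raise GenerationError("n_per_class must be >= 1")
    out = Path(out_dir)
    rows = []
    for ci, profile in enumerate(profiles):
        img_dir = out / profile.class_name / "images"
        msk_dir = out / profile.class_name / "masks"
        img_dir.mkdir(parents=True, exist_ok=True)
        msk_dir.mkdir(parents=True, exist_ok=True)
        for i in range(n_per_class):
            seed = _case_seed(rng_seed, ci, i)
            image, mask = generate_synthetic_case(profile, seed)
            if augment:
                rng = np.random.default_rng(seed + 1)
                image, mask = augment_pair(image, mask, sample_augment_ops(rng))
            stem = f"{profile.class_name}_{i:04d}.png"
            save_image_png(img_dir / stem, image)
            save_mask_png(msk_dir / stem, mask)
            rows.append(
                {
                    "class": profile.class_name,
                    "image_path": str(Path(profile.class_name) / "images" / stem),
                    "mask_path": str(Path(profile.class_name) / "masks" / stem),
                    "seed": seed,
                }
            )
    manifest = pd.DataFrame(rows, columns=["class", "image_path", "mask_path", "seed"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
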