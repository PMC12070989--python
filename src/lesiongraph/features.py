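"""Per-region geometric, texture (GLCM) and intensity features with CSV serialization.

Each connected region of a labeled mask yields a 14-dimensional feature vector:
nine geometric descriptors, four Haralick texture statistics from a
region-restricted gray-level co-occurrence matrix, and mean intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .errors import EmptyMaskError, FormatError, PairingError, UndefinedTextureError
from .synth import validate_mask


def _check_image(image: np.ndarray) -> np.ndarray:
    """2D, finite, [0,1] — no minimum-size requirement (toy inputs allowed)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise PairingError(f"image must be 2D, got shape {image.shape}")
    if not np.isfinite(image).all() or image.min() < 0 or image.max() > 1:
        raise PairingError("image intensities must be finite and in [0, 1]")
    return image

#: Feature column order used everywhere (CSV, node attributes, arrays).
FEATURE_NAMES = (
    "area",
    "perimeter",
    "eccentricity",
    "solidity",
    "major_axis",
    "minor_axis",
    "aspect_ratio",
    "compactness",
    "circularity",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_energy",
    "glcm_homogeneity",
    "mean_intensity",
)

CSV_HEADER = ("class", "region_id") + FEATURE_NAMES

__all__ = [
    "FEATURE_NAMES",
    "CSV_HEADER",
    "Region",
    "RegionFeatureVector",
    "FeatureTable",
    "GlcmConfig",
    "extract_regions",
    "geometric_features",
    "glcm_matrix",
    "glcm_features",
    "extract_feature_table",
    "write_csv",
    "read_csv",
]


@dataclass(frozen=True)
class Region:
    """One connected component: its positive mask label and pixel coordinates."""

    label: int
    coords: np.ndarray  # (n_pixels, 2) array of (row, col)

    @property
    def area(self) -> int:
        return len(self.coords)


@dataclass
class RegionFeatureVector:
    region_id: int
    area: float
    perimeter: float
    eccentricity: float
    solidity: float
    major_axis: float
    minor_axis: float
    aspect_ratio: float
    compactness: float
    circularity: float
    glcm_contrast: float
    glcm_correlation: float
    glcm_energy: float
    glcm_homogeneity: float
    mean_intensity: float

    def as_array(self) -> np.ndarray:
        """The 14 features (region_id excluded) in FEATURE_NAMES order."""
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    def validate(self) -> None:
        if self.area <= 0:
            raise FormatError("area must be > 0")
        if self.minor_axis > self.major_axis + 1e-9:
            raise FormatError("minor_axis must not exceed major_axis")
        if not -1.0 - 1e-9 <= self.glcm_correlation <= 1.0 + 1e-9:
            raise FormatError("glcm_correlation must lie in [-1, 1]")
        if not 0.0 <= self.eccentricity < 1.0:
            raise FormatError("eccentricity must lie in [0, 1)")


@dataclass
class FeatureTable:
    """All region feature vectors of one image+mask pair (one class)."""

    class_label: str
    rows: list[RegionFeatureVector]
    image_path: str = ""
    mask_path: str = ""

    def __post_init__(self):
        ids = [r.region_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate region_ids in table: {ids}")

    def __len__(self) -> int:
        return len(self.rows)

    def feature_matrix(self) -> np.ndarray:
        return np.array([r.as_array() for r in self.rows], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        data = {"class": [self.class_label] * len(self.rows)}
        data["region_id"] = [r.region_id for r in self.rows]
        mat = self.feature_matrix()
        for j, name in enumerate(FEATURE_NAMES):
            data[name] = mat[:, j] if len(self.rows) else []
        return pd.DataFrame(data, columns=list(CSV_HEADER))

    def approx_equal(self, other: "FeatureTable", rtol: float = 1e-9) -> bool:
        if self.class_label != other.class_label or len(self) != len(other):
            return False
        if [r.region_id for r in self.rows] != [r.region_id for r in other.rows]:
            return False
        return bool(
            np.allclose(self.feature_matrix(), other.feature_matrix(), rtol=rtol, atol=1e-12)
        )


@dataclass(frozen=True)
class GlcmConfig:
    """Region-restricted co-occurrence configuration.

    Intensities are quantized into ``levels`` equal bins over [0, 1]; pairs are
    counted only where both pixels belong to the region, for every
    (distance, angle) offset, optionally symmetrized and normalized.
    """

    levels: int = 32
    distances: tuple[int, ...] = (1,)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self):
        if self.levels < 2:
            raise FormatError("GLCM levels must be >= 2")
        if any(d <= 0 for d in self.distances):
            raise FormatError("GLCM distances must be positive")

    def offsets(self) -> list[tuple[int, int]]:
        base = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
        out = []
        for d in self.distances:
            for a in self.angles:
                if a not in base:
                    raise FormatError(f"unsupported GLCM angle {a}; use 0/45/90/135")
                dr, dc = base[a]
                out.append((dr * d, dc * d))
        return out


# ---------------------------------------------------------------------------
# region extraction


def extract_regions(mask: np.ndarray) -> list[Region]:
    """Connected components (8-connectivity) of every positive label.

    Regions are ordered by ascending mask label, then by scanline order of
    each component's first pixel.  Raises EmptyMaskError on all-zero masks.
    """
    mask = validate_mask(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise EmptyMaskError("mask has no foreground regions")
    regions: list[Region] = []
    for lab in labels:
        comp = measure.label(mask == lab, connectivity=2)
        comps = []
        for cid in range(1, comp.max() + 1):
            coords = np.argwhere(comp == cid)  # argwhere is scanline-ordered
            comps.append(coords)
        comps.sort(key=lambda c: (int(c[0, 0]), int(c[0, 1])))
        regions.extend(Region(label=int(lab), coords=c) for c in comps)
    return regions


# ---------------------------------------------------------------------------
# geometric features

_AXIS_FLOOR = 1.0  # px; guards single-pixel / 1-px-wide degeneracies
_ECC_CEIL = 1.0 - 1e-12


def geometric_features(region: Region) -> dict[str, float]:
    """Shape descriptors of one region.

    area = pixel count; perimeter from the border-pixel chain estimator
    (diagonal steps weighted sqrt(2)); eccentricity and axis lengths from the
    moment-equivalent ellipse; solidity = area / convex hull area;
    circularity = 4*pi*A/P^2 and compactness its reciprocal.
    """
    coords = region.coords
    if len(coords) == 0:
        raise EmptyMaskError("empty region")
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    binary = np.zeros((rmax - rmin + 3, cmax - cmin + 3), dtype=bool)
    binary[coords[:, 0] - rmin + 1, coords[:, 1] - cmin + 1] = True

    area = float(len(coords))
    perimeter = float(measure.perimeter(binary, neighborhood=4))
    if perimeter <= 0:  # single pixel
        perimeter = _AXIS_FLOOR
        warnings.warn("degenerate region: perimeter floored to 1 px", stacklevel=2)
    props = measure.regionprops(binary.astype(np.uint8))[0]
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    ecc = float(props.eccentricity)
    if minor < _AXIS_FLOOR:
        minor = _AXIS_FLOOR
    major = max(major, minor)
    ecc = min(max(ecc, 0.0), _ECC_CEIL)
    solidity = float(props.solidity)
    circularity = 4.0 * np.pi * area / perimeter**2
    return {
        "area": area,
        "perimeter": perimeter,
        "eccentricity": ecc,
        "solidity": solidity,
        "major_axis": major,
        "minor_axis": minor,
        "aspect_ratio": major / minor,
        "compactness": 1.0 / circularity,
        "circularity": circularity,
    }


# ---------------------------------------------------------------------------
# GLCM texture features


def _quantize(image: np.ndarray, levels: int) -> np.ndarray:
    return np.clip((image * levels).astype(np.int64), 0, levels - 1)


def glcm_matrix(
    image: np.ndarray,
    region: Region,
    cfg: GlcmConfig,
    offset: tuple[int, int],
) -> tuple[np.ndarray, int]:
    """Co-occurrence counts for one offset, restricted to region-interior pairs.

    Returns (matrix, n_raw_pairs); the matrix is symmetrized/normalized per cfg.
    """
    coords = region.coords
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    sub = image[rmin : rmax + 1, cmin : cmax + 1]
    inreg = np.zeros(sub.shape, dtype=bool)
    inreg[coords[:, 0] - rmin, coords[:, 1] - cmin] = True
    q = _quantize(sub, cfg.levels)

    dr, dc = offset
    h, w = sub.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    mat = np.zeros((cfg.levels, cfg.levels), dtype=float)
    if r0 >= r1 or c0 >= c1:
        return mat, 0
    valid = inreg[r0:r1, c0:c1] & inreg[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    a = q[r0:r1, c0:c1][valid]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc][valid]
    np.add.at(mat, (a, b), 1.0)
    n_pairs = int(valid.sum())
    if cfg.symmetric:
        mat = mat + mat.T
    if cfg.normalize and mat.sum() > 0:
        mat = mat / mat.sum()
    return mat, n_pairs


def _haralick(p: np.ndarray) -> tuple[float, float, float, float]:
    """(contrast, correlation, energy, homogeneity) of a normalized GLCM."""
    levels = p.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    contrast = float((p * (i - j) ** 2).sum())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    energy = float((p**2).sum())
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    var_i = float((p * (i - mu_i) ** 2).sum())
    var_j = float((p * (j - mu_j) ** 2).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0  # constant region convention
    else:
        cov = float((p * (i - mu_i) * (j - mu_j)).sum())
        correlation = cov / np.sqrt(var_i * var_j)
    return contrast, correlation, energy, homogeneity


def glcm_features(
    image: np.ndarray, region: Region, cfg: GlcmConfig | None = None
) -> tuple[float, float, float, float]:
    """Haralick (contrast, correlation, energy, homogeneity) averaged over offsets.

    Offsets contributing no region-interior pair are dropped from the average;
    fewer than 2 co-occurring pairs in total raises UndefinedTextureError.
    """
    cfg = cfg or GlcmConfig()
    image = _check_image(image)
    stats = []
    total_pairs = 0
    for offset in cfg.offsets():
        # stats always come from a normalized matrix regardless of cfg.normalize
        mat, n_pairs = glcm_matrix(image, region, replace(cfg, normalize=True), offset)
        total_pairs += n_pairs
        if n_pairs > 0:
            stats.append(_haralick(mat))
    if total_pairs < 2 or not stats:
        raise UndefinedTextureError(
            f"region too small for texture: {total_pairs} co-occurring pair(s)"
        )
    arr = np.asarray(stats)
    contrast, correlation, energy, homogeneity = arr.mean(axis=0)
    return float(contrast), float(correlation), float(energy), float(homogeneity)


# ---------------------------------------------------------------------------
# full table extraction


def extract_feature_table(
    image: np.ndarray,
    mask: np.ndarray,
    class_label: str,
    cfg: GlcmConfig | None = None,
    image_path: str = "",
    mask_path: str = "",
) -> FeatureTable:
    """One feature row per connected region, in deterministic region order."""
    image = _check_image(image)
    mask = validate_mask(mask, image)
    cfg = cfg or GlcmConfig()
    rows = []
    for rid, region in enumerate(extract_regions(mask), start=1):
        geo = geometric_features(region)
        contrast, correlation, energy, homogeneity = glcm_features(image, region, cfg)
        mean_intensity = float(image[region.coords[:, 0], region.coords[:, 1]].mean())
        rows.append(
            RegionFeatureVector(
                region_id=rid,
                glcm_contrast=contrast,
                glcm_correlation=correlation,
                glcm_energy=energy,
                glcm_homogeneity=homogeneity,
                mean_intensity=mean_intensity,
                **geo,
            )
        )
    return FeatureTable(
        class_label=class_label, rows=rows, image_path=image_path, mask_path=mask_path
    )


# ---------------------------------------------------------------------------
# CSV serialization (10 significant digits, fixed header)


def write_csv(table: FeatureTable, path, mode: str = "w") -> None:
    if len(table.rows) == 0:
        raise FormatError("refusing to write a feature table with no rows")
    path = Path(path)
    write_header = mode == "w" or not path.exists()
    with open(path, mode) as fh:
        if write_header:
            fh.write(",".join(CSV_HEADER) + "\n")
        for row in table.rows:
            vals = [table.class_label, str(row.region_id)]
            vals += [f"{v:.10g}" for v in row.as_array()]
            fh.write(",".join(vals) + "\n")


def read_csv(path) -> FeatureTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if tuple(header) != CSV_HEADER:
        raise FormatError(
            f"feature CSV header mismatch: expected {CSV_HEADER}, got {tuple(header)}"
        )
    df = pd.read_csv(path)
    if len(df) == 0:
        raise FormatError("feature CSV has no rows")
    classes = df["class"].unique()
    if len(classes) != 1:
        raise FormatError(f"feature CSV must hold a single class, got {list(classes)}")
    rows = [
        RegionFeatureVector(
            region_id=int(rec["region_id"]),
            **{name: float(rec[name]) for name in FEATURE_NAMES},
        )
        for rec in df.to_dict("records")
    ]
    return FeatureTable(class_label=str(classes[0]), rows=rows)
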