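"""Gray-level carcass image measurement.

The measurement chain mirrors the image-processing protocol of the carcass
grading method this package implements: convert to 8-bit gray, outline the
carcass, compute the carcass mean gray level, then threshold the gray scale
to separate the brighter fat cover from the darker muscle and express the
fat pixels as a percentage of the carcass area ("carcass fat area").

Per-carcass optimum thresholds in the calibration study ranged from 100 to
112 depending on fat and muscle color; the method standardizes on the single
mean value of that range, 106, with fat defined as gray STRICTLY greater
than the threshold (a pixel at exactly 106 is muscle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "CALIBRATION_THRESHOLD_RANGE",
    "DEFAULT_THRESHOLD",
    "DEFAULT_BACKGROUND_THRESHOLD",
    "SegmentationResult",
    "to_gray8",
    "extract_carcass_mask",
    "mean_gray_level",
    "segment_fat",
    "fat_area_percent",
    "optimal_threshold",
    "measure_array",
    "measure_image",
]

#: span of per-carcass optimum gray thresholds observed in calibration
CALIBRATION_THRESHOLD_RANGE = (100, 112)
#: single standardized threshold: the mean of the calibration range
DEFAULT_THRESHOLD = round(sum(CALIBRATION_THRESHOLD_RANGE) / 2)
DEFAULT_BACKGROUND_THRESHOLD = 20

_STRUCTURE4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass(frozen=True)
class SegmentationResult:
    """Carcass and fat masks plus the derived scalar measurements."""

    carcass_mask: np.ndarray  # bool
    fat_mask: np.ndarray  # bool, subset of carcass_mask
    mean_gray: float  # 0-255 scale, real-valued
    fat_area_pct: float  # % of carcass area
    threshold_used: int

    @property
    def carcass_pixels(self) -> int:
        return int(self.carcass_mask.sum())

    @property
    def fat_pixels(self) -> int:
        return int(self.fat_mask.sum())


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        return to_gray8(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D gray or 3-channel image, got shape {img.shape}")
    return img


def to_gray8(color: np.ndarray) -> np.ndarray:
    """Convert a 3-channel 0-255 image to 8-bit gray.

    ITU-R BT.601 luma, rounded half-up: 0.299 R + 0.587 G + 0.114 B.
    """
    color = np.asarray(color, dtype=np.float64)
    if color.ndim != 3 or color.shape[-1] != 3:
        raise ValueError(f"expected a (rows, cols, 3) image, got shape {color.shape}")
    luma = 0.299 * color[..., 0] + 0.587 * color[..., 1] + 0.114 * color[..., 2]
    return np.floor(luma + 0.5).astype(np.uint8)


def extract_carcass_mask(img: np.ndarray, background_threshold: int = DEFAULT_BACKGROUND_THRESHOLD) -> np.ndarray:
    """Outline the carcass as the largest bright 4-connected component.

    Pixels with gray > background_threshold are candidate foreground; the
    largest 4-connected component is kept and its interior holes filled, so
    the result is exactly one connected region.
    """
    img = _as_gray(img)
    if img.size == 0:
        raise ValueError("empty image")
    above = img > background_threshold
    if not above.any():
        raise ValueError("no carcass found (no pixel above background threshold)")
    labels, nlab = ndimage.label(above, structure=_STRUCTURE4)
    sizes = ndimage.sum_labels(above, labels, index=np.arange(1, nlab + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def _check_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("mask shape does not match image shape")
    return mask


def mean_gray_level(img: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean gray over mask pixels (fat and muscle both included)."""
    img = _as_gray(img)
    mask = _check_mask(img, mask)
    if not mask.any():
        raise ValueError("empty mask")
    return float(img[mask].mean())


def segment_fat(img: np.ndarray, mask: np.ndarray, threshold: int = DEFAULT_THRESHOLD) -> np.ndarray:
    """Fat mask: carcass pixels with gray strictly greater than threshold."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    img = _as_gray(img)
    mask = _check_mask(img, mask)
    return mask & (img > threshold)


def fat_area_percent(fat_mask: np.ndarray, carcass_mask: np.ndarray) -> float:
    """Carcass fat area: 100 * |fat| / |carcass|, on a 0-100 scale."""
    fat_mask = np.asarray(fat_mask, dtype=bool)
    carcass_mask = np.asarray(carcass_mask, dtype=bool)
    if (fat_mask & ~carcass_mask).any():
        raise ValueError("fat mask must be a subset of the carcass mask")
    n = int(carcass_mask.sum())
    if n == 0:
        raise ValueError("empty carcass mask")
    return 100.0 * float(fat_mask.sum()) / n


def optimal_threshold(img: np.ndarray, carcass_mask: np.ndarray, reference_fat_mask: np.ndarray) -> int:
    """Best single gray threshold against a reference fat mask.

    Scans T in [0, 255] and minimizes the number of carcass pixels
    misclassified by the strict greater-than rule versus the reference mask;
    among tied thresholds, returns the midpoint (rounded down) of the
    minimizing range — for perfectly separated constant-intensity classes
    this is the class midpoint.
    """
    img = _as_gray(img)
    carcass_mask = _check_mask(img, carcass_mask)
    reference_fat_mask = _check_mask(img, reference_fat_mask)
    if not carcass_mask.any():
        raise ValueError("empty carcass mask")
    if (reference_fat_mask & ~carcass_mask).any():
        raise ValueError("reference fat mask must be a subset of the carcass mask")
    if not reference_fat_mask.any():
        warnings.warn("empty reference fat mask; returning 255 (nothing labeled fat)")
        return 255

    fat_vals = img[reference_fat_mask]
    muscle_vals = img[carcass_mask & ~reference_fat_mask]
    fat_cum = np.cumsum(np.bincount(fat_vals, minlength=256))  # #fat <= T
    muscle_cum = np.cumsum(np.bincount(muscle_vals, minlength=256))
    errors = fat_cum + (muscle_vals.size - muscle_cum)  # fat missed + muscle kept
    ties = np.flatnonzero(errors == errors.min())
    return int((ties[0] + ties[-1]) // 2)


def measure_array(
    img: np.ndarray,
    threshold: int = DEFAULT_THRESHOLD,
    background_threshold: int = DEFAULT_BACKGROUND_THRESHOLD,
) -> SegmentationResult:
    """Full measurement of one in-memory image: outline, mean gray, fat area."""
    gray = _as_gray(img)
    carcass = extract_carcass_mask(gray, background_threshold)
    mg = mean_gray_level(gray, carcass)
    fat = segment_fat(gray, carcass, threshold)
    fa = fat_area_percent(fat, carcass)
    return SegmentationResult(
        carcass_mask=carcass,
        fat_mask=fat,
        mean_gray=mg,
        fat_area_pct=fa,
        threshold_used=int(threshold),
    )


def measure_image(
    path: str | Path,
    threshold: int = DEFAULT_THRESHOLD,
    background_threshold: int = DEFAULT_BACKGROUND_THRESHOLD,
) -> SegmentationResult:
    """Measure one image file (8-bit gray or 24-bit RGB PNG/TIFF)."""
    path = Path(path)
    try:
        img = iio.imread(path)
        return measure_array(img, threshold, background_threshold)
    except Exception as exc:
        raise type(exc)(f"{path}: {exc}") from exc
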