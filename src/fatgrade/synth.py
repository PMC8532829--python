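"""Synthetic carcass cohorts and carcass images with known ground truth.

No per-animal data are published for the calibration study this package
emulates, so analyses run on synthetic cohorts: tabular records (SEUROP
fatness score, hot carcass weight, cutting fat) drawn group-by-group from
the published group means and standard errors, plus rendered half-carcass
images in which subcutaneous fat is brighter than muscle, so that a gray
threshold near 106 separates the two tissues.

Calibration targets (group means +- se, groups = SEUROP scores 3..6 with
n = 9/6/28/7): HCW 360/358/363/347 kg, cutting fat 4.2/6.4/9.2/12.8 %,
carcass fat area 25.0/31.5/41.7/48.4 %.  Muscle/fat gray means 56/145 are
obtained by fitting mean_gray = a + b*fat_fraction through the end points
(f=25.0, g=78) and (f=48.4, g=99) and extrapolating to f=0 and f=100; they
are a calibration of this generator, not a measured tissue property.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "GroupParams",
    "CohortConfig",
    "ImageGenConfig",
    "GroundTruth",
    "Cohort",
    "score_label",
    "generate_cohort",
    "generate_carcass_image",
    "write_fixture_set",
    "weighted_overall_means",
    "noise_free",
]

GENERATOR_VERSION = "1.0"

#: columns of the cohort CSV, in order
COHORT_CSV_COLUMNS = [
    "animal_id",
    "seurop_score",
    "seurop_label",
    "hcw_kg",
    "cutting_fat_pct",
    "true_fat_fraction_pct",
    "image_path",
    "carcass_mask_path",
    "fat_mask_path",
    "seed",
]


@dataclass(frozen=True)
class GroupParams:
    """Per-fatness-score sampling parameters (means and standard errors).

    The published summaries report mean +- se per score group; sampling needs
    per-animal SDs, recovered as sd = se * sqrt(n).
    """

    n: int
    hcw_mean: float  # kg
    hcw_se: float
    cutfat_mean: float  # % of carcass weight
    cutfat_se: float
    fatarea_mean: float  # % of carcass surface
    fatarea_se: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        for se in (self.hcw_se, self.cutfat_se, self.fatarea_se):
            if se < 0:
                raise ValueError("standard errors must be >= 0")
        if not 0.0 <= self.fatarea_mean <= 100.0:
            raise ValueError("fat-area mean must lie in [0, 100]")

    @property
    def hcw_sd(self) -> float:
        return self.hcw_se * math.sqrt(self.n)

    @property
    def cutfat_sd(self) -> float:
        return self.cutfat_se * math.sqrt(self.n)

    @property
    def fatarea_sd(self) -> float:
        return self.fatarea_se * math.sqrt(self.n)


def _default_groups() -> dict[int, GroupParams]:
    # Calibration reference: 50-bull cohort, SEUROP fatness scores 3..6.
    return {
        3: GroupParams(9, 360.0, 12.2, 4.2, 0.3, 25.0, 1.4),
        4: GroupParams(6, 358.0, 7.1, 6.4, 0.5, 31.5, 2.4),
        5: GroupParams(28, 363.0, 6.8, 9.2, 0.4, 41.7, 1.8),
        6: GroupParams(7, 347.0, 11.3, 12.8, 0.9, 48.4, 2.8),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Cohort sampling configuration.

    ``rho`` is the within-group correlation between true fat fraction and
    cutting fat.  It is a free calibration knob (the published summaries give
    no within-group covariance); 0.6 places the cohort-level R^2 of the
    fat-area regression near the 0.66-0.72 band of the calibration study.
    """

    groups: dict[int, GroupParams] = field(default_factory=_default_groups)
    rho: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups.values())


@dataclass(frozen=True)
class ImageGenConfig:
    """Rendering parameters for one synthetic half-carcass image.

    Gray means 56 (muscle) and 145 (fat) are the two-point calibration of the
    mixture mean against the published group gray levels; the +-6 per-image
    brightness jitter makes per-image optimum thresholds spread over roughly
    a dozen gray levels, emulating carcass-to-carcass fat/muscle color
    variation.
    """

    shape: tuple[int, int] = (192, 144)  # rows, cols
    background_gray: int = 0
    muscle_mean: float = 56.0
    muscle_sd: float = 12.0
    fat_mean: float = 145.0
    fat_sd: float = 12.0
    jitter: float = 6.0  # uniform +-jitter gray levels per image
    smooth: float = 8.0  # gaussian sigma of the fat-patch field, px
    coverage: float = 0.45  # silhouette fraction of the frame
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.muscle_mean, self.fat_mean, float(self.background_gray)):
            if not 0.0 <= v <= 255.0:
                raise ValueError("gray parameters must lie in [0, 255]")
        if self.muscle_mean + self.jitter >= self.fat_mean - self.jitter:
            raise ValueError("muscle and fat gray classes are not separable")
        if not 0.0 < self.coverage < 1.0:
            raise ValueError("coverage must lie in (0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Reference masks emitted alongside a rendered image."""

    carcass_mask: np.ndarray  # bool, rows x cols
    fat_mask: np.ndarray  # bool, subset of carcass_mask
    fat_fraction: float  # %, = 100 * |fat| / |carcass| up to pixel rounding


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of animal records plus provenance."""

    table: pd.DataFrame
    config: CohortConfig
    seed: int

    def __len__(self) -> int:
        return len(self.table)


def score_label(score: int) -> str:
    """Map the 1-15 SEUROP fatness score to its class label.

    1 -> "1-", 2 -> "1", 3 -> "1+", 4 -> "2-", ..., 15 -> "5+".
    """
    if not 1 <= score <= 15:
        raise ValueError(f"SEUROP score must lie in [1, 15], got {score}")
    cls = (score + 2) // 3
    sub = ("-", "", "+")[(score - 1) % 3]
    return f"{cls}{sub}"


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, lo: float, hi: float
) -> np.ndarray:
    """Normal(mean, sd) truncated to [lo, hi] by resampling."""
    out = rng.normal(mean, sd, size=n)
    for _ in range(1000):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise RuntimeError("truncated-normal resampling did not converge")


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Draw one cohort of carcass records.

    Per score group s: hcw ~ N(mu_s, se_s*sqrt(n_s)) truncated to > 0;
    true_fat_fraction ~ N truncated to [0, 100]; cutting fat follows the
    within-group linear model

        cutting_fat = muCF_s + beta_s*(fat - muFA_s) + eps,
        beta_s = rho * sdCF_s / sdFA_s,   eps ~ N(0, sdCF_s*sqrt(1 - rho^2)),

    truncated to >= 0, so that within each group cutting fat has mean muCF_s,
    SD sdCF_s and correlation rho with the fat fraction.  Deterministic given
    (config, config.seed).
    """
    config = config or CohortConfig()
    if config.n_total == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(config.seed)

    rows: list[dict] = []
    idx = 0
    for score in sorted(config.groups):
        g = config.groups[score]
        if g.n == 0:
            continue
        hcw = _truncated_normal(rng, g.hcw_mean, g.hcw_sd, g.n, 1e-9, math.inf)
        fat = _truncated_normal(rng, g.fatarea_mean, g.fatarea_sd, g.n, 0.0, 100.0)
        beta = (
            config.rho * g.cutfat_sd / g.fatarea_sd if g.fatarea_sd > 0 else 0.0
        )
        eps_sd = g.cutfat_sd * math.sqrt(1.0 - config.rho**2)
        loc = g.cutfat_mean + beta * (fat - g.fatarea_mean)
        cutfat = np.empty(g.n)
        for i in range(g.n):
            cutfat[i] = _truncated_normal(rng, loc[i], eps_sd, 1, 0.0, math.inf)[0]
        for i in range(g.n):
            idx += 1
            rows.append(
                {
                    "animal_id": f"A{idx:03d}",
                    "seurop_score": score,
                    "seurop_label": score_label(score),
                    "hcw_kg": hcw[i],
                    "cutting_fat_pct": cutfat[i],
                    "true_fat_fraction_pct": fat[i],
                }
            )
    table = pd.DataFrame(rows)
    table["mean_gray"] = np.nan  # filled after measurement
    table["fat_area_pct"] = np.nan
    return Cohort(table=table, config=config, seed=config.seed)


def _silhouette(
    rng: np.random.Generator, shape: tuple[int, int], coverage: float
) -> np.ndarray:
    """Single connected smoothed-blob silhouette covering ~coverage of the frame.

    Star-convex radial blob: base radius set from the target area, perturbed
    by a few low-order harmonics, clipped to fit the frame.
    """
    rows, cols = shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    r0 = math.sqrt(coverage * rows * cols / math.pi)
    cap = min(rows, cols) / 2.0 - 1.5

    theta_tab = np.linspace(0.0, 2.0 * math.pi, 512, endpoint=False)
    radius_tab = np.full(512, r0)
    for k in range(2, 7):
        amp = rng.uniform(0.0, 0.045)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        radius_tab += r0 * amp * np.cos(k * theta_tab + phase)
    radius_tab = np.clip(radius_tab, 4.0, cap)

    yy, xx = np.mgrid[0:rows, 0:cols]
    theta = np.arctan2(yy - cy, xx - cx) % (2.0 * math.pi)
    dist = np.hypot(yy - cy, xx - cx)
    r_at = np.interp(theta, theta_tab, radius_tab, period=2.0 * math.pi)
    mask = dist <= r_at

    # guarantee the stated invariants regardless of harmonic draw
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, nlab = ndimage.label(mask, structure=structure)
    if nlab > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, nlab + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def generate_carcass_image(
    record: pd.Series | dict,
    config: ImageGenConfig | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one 8-bit grayscale half-carcass image plus its ground truth.

    The fat mask is the top f% of carcass pixels ranked by a smoothed random
    field, so the mask ratio equals the record's true fat fraction up to
    pixel rounding.  Fat/muscle pixels are drawn from the two gray
    distributions, shifted by one per-image brightness jitter, clipped to
    [0, 255] and quantized to 8 bits.
    """
    config = config or ImageGenConfig()
    rows, cols = config.shape
    if rows < 32 or cols < 32:
        raise ValueError("frame too small to host a silhouette (min 32x32)")
    f = float(record["true_fat_fraction_pct"])
    if not 0.0 <= f <= 100.0:
        raise ValueError("true_fat_fraction_pct must lie in [0, 100]")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    carcass = _silhouette(rng, config.shape, config.coverage)
    npix = int(carcass.sum())

    field_ = ndimage.gaussian_filter(
        rng.random(config.shape), sigma=config.smooth, mode="reflect"
    )
    fat = np.zeros_like(carcass)
    k = int(round(f / 100.0 * npix))
    if k > 0:
        vals = field_[carcass]
        order = np.argsort(-vals, kind="stable")
        flat_idx = np.flatnonzero(carcass.ravel())[order[:k]]
        fat.ravel()[flat_idx] = True

    jitter = rng.uniform(-config.jitter, config.jitter) if config.jitter > 0 else 0.0
    img = np.full(config.shape, float(config.background_gray))
    muscle = carcass & ~fat
    img[muscle] = rng.normal(config.muscle_mean + jitter, config.muscle_sd, int(muscle.sum()))
    img[fat] = rng.normal(config.fat_mean + jitter, config.fat_sd, k)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        carcass_mask=carcass, fat_mask=fat, fat_fraction=100.0 * k / npix
    )
    return img, truth


def noise_free(config: ImageGenConfig | None = None) -> ImageGenConfig:
    """Copy of ``config`` with intensity noise and brightness jitter disabled."""
    config = config or ImageGenConfig()
    return dataclasses.replace(config, muscle_sd=0.0, fat_sd=0.0, jitter=0.0)


def _per_animal_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive one image seed per animal from the cohort seed (stream 1)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), 1]))
    return rng.integers(0, 2**31 - 1, size=n)


def write_fixture_set(
    cohort: Cohort,
    image_config: ImageGenConfig | None = None,
    directory: str | Path = ".",
) -> dict:
    """Write images, ground-truth masks, cohort CSV and manifest to disk.

    One grayscale PNG + two mask PNGs (values {0, 255}) per animal, a cohort
    CSV with per-animal file paths and image seeds, and a plain-text
    manifest.  Re-running with the same cohort seed reproduces the CSV
    byte-for-byte.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    image_config = image_config or ImageGenConfig()
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)

    seeds = _per_animal_seeds(cohort.seed, len(cohort))
    out = cohort.table.copy()
    img_paths, cmask_paths, fmask_paths = [], [], []
    for (_, rec), s in zip(out.iterrows(), seeds):
        img, truth = generate_carcass_image(rec, image_config, seed=int(s))
        aid = rec["animal_id"]
        p_img = directory / "images" / f"{aid}.png"
        p_cm = directory / "masks" / f"{aid}_carcass.png"
        p_fm = directory / "masks" / f"{aid}_fat.png"
        iio.imwrite(p_img, img)
        iio.imwrite(p_cm, truth.carcass_mask.astype(np.uint8) * 255)
        iio.imwrite(p_fm, truth.fat_mask.astype(np.uint8) * 255)
        img_paths.append(str(p_img.relative_to(directory)))
        cmask_paths.append(str(p_cm.relative_to(directory)))
        fmask_paths.append(str(p_fm.relative_to(directory)))

    out["image_path"] = img_paths
    out["carcass_mask_path"] = cmask_paths
    out["fat_mask_path"] = fmask_paths
    out["seed"] = seeds
    csv_path = directory / "cohort.csv"
    out[COHORT_CSV_COLUMNS].to_csv(csv_path, index=False, float_format="%.6f")

    manifest_path = directory / "manifest.txt"
    lines = [
        f"generator_version: {GENERATOR_VERSION}",
        f"cohort_seed: {cohort.seed}",
        f"cohort_config: {cohort.config}",
        f"image_config: {image_config}",
        f"n_animals: {len(cohort)}",
    ]
    manifest_path.write_text("\n".join(lines) + "\n")

    return {
        "cohort_csv": str(csv_path),
        "manifest": str(manifest_path),
        "images": img_paths,
        "carcass_masks": cmask_paths,
        "fat_masks": fmask_paths,
    }


def weighted_overall_means(config: CohortConfig | None = None) -> dict[str, float]:
    """Group-size-weighted overall means of the configured group means."""
    config = config or CohortConfig()
    n = config.n_total
    if n == 0:
        raise ValueError("empty cohort")
    out = {"n": float(n)}
    for name, attr in [
        ("hcw_kg", "hcw_mean"),
        ("cutting_fat_pct", "cutfat_mean"),
        ("fat_area_pct", "fatarea_mean"),
    ]:
        out[name] = sum(g.n * getattr(g, attr) for g in config.groups.values()) / n
    return out
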