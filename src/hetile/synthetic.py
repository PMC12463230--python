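"""Seeded synthetic H&E-like cohort generator.

Emulates the statistical structure the tile pipeline assumes: per-slide
bulk trait values, near-white background vs pink tissue, dark nucleus-like
blobs whose areal density increases monotonically with a latent continuous
trait, spatially contiguous heterogeneity patches where the local trait
level is resampled, and three slides per patient taken at distinct
timepoints. A per-pixel ``truth_map`` of the local trait level is kept for
validation only and is never consumed by pipeline stages.

The first entry in ``trait_specs`` drives stain density; additional traits
are noisy monotone transforms of the driving level (rank-mapped to
[0, 100] for continuous traits, median-thresholded for binary), so a
``signal_strength`` of 0 yields a pure-noise trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from scipy import ndimage

__all__ = ["TraitSpec", "CohortSpec", "SlideRecord", "generate_cohort", "write_cohort"]

# rendering palette (8-bit RGB)
TISSUE_RGB = np.array([236, 180, 200], dtype=np.float32)   # eosin-like pink
NUCLEUS_RGB = np.array([88, 54, 128], dtype=np.float32)    # hematoxylin-like purple
BACKGROUND_MIN = 235                                       # >= whiteness threshold 220


@dataclass(frozen=True)
class TraitSpec:
    """One slide-level trait: ``continuous`` (values on [0, 100]) or ``binary``."""

    name: str
    kind: str = "continuous"
    signal_strength: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"trait kind must be continuous|binary, got {self.kind!r}")
        if self.signal_strength < 0 or self.noise_sd < 0:
            raise ValueError("signal_strength and noise_sd must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int
    timepoints_per_patient: int = 3
    image_height: int = 512
    image_width: int = 512
    tile_size: int = 128
    trait_specs: tuple[TraitSpec, ...] = field(
        default_factory=lambda: (TraitSpec("Ki67"),))
    background_fraction: float = 0.25
    heterogeneity_patch_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.timepoints_per_patient < 1:
            raise ValueError("timepoints_per_patient must be >= 1")
        if self.image_height % self.tile_size or self.image_width % self.tile_size:
            raise ValueError(
                f"image dimensions ({self.image_height}x{self.image_width}) must be "
                f"multiples of tile_size={self.tile_size}")
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background_fraction must lie in [0, 1)")
        if not (0 <= self.heterogeneity_patch_fraction < 1):
            raise ValueError("heterogeneity_patch_fraction must lie in [0, 1)")
        names = [t.name for t in self.trait_specs]
        if len(set(names)) != len(names):
            raise ValueError("trait names must be unique within a cohort")
        if not self.trait_specs:
            raise ValueError("at least one trait required")


@dataclass
class SlideRecord:
    """One biopsy image plus its bulk trait values and patient/timepoint identity."""

    slide_id: str
    patient_id: str
    timepoint: int
    image: np.ndarray                     # (H, W, 3) uint8
    traits: dict[str, float]
    truth_map: np.ndarray | None = None   # (H, W) float32, local driving-trait level


def _smooth_field(rng: np.random.Generator, h: int, w: int, cells: int = 8) -> np.ndarray:
    """Low-frequency random field in [0,1] via bilinear upsampling of coarse noise."""
    coarse = rng.random((cells, cells))
    zy = np.linspace(0, cells - 1, h)
    zx = np.linspace(0, cells - 1, w)
    field = ndimage.map_coordinates(coarse, np.meshgrid(zy, zx, indexing="ij"),
                                    order=1, mode="nearest")
    lo, hi = field.min(), field.max()
    return (field - lo) / (hi - lo + 1e-12)


def _tissue_mask(rng: np.random.Generator, h: int, w: int, background_fraction: float) -> np.ndarray:
    """Contiguous-ish tissue mask covering ~ (1 - background_fraction) of the slide."""
    if background_fraction == 0:
        return np.ones((h, w), dtype=bool)
    field = _smooth_field(rng, h, w)
    cut = np.quantile(field, background_fraction)
    return field > cut


def _patch_labels(rng: np.random.Generator, tissue: np.ndarray, frac: float) -> np.ndarray:
    """Integer map: 0 = bulk tissue, k>0 = k-th heterogeneity patch.

    Disks are dropped at random tissue locations until ~``frac`` of the
    tissue area is covered; overlaps keep the later patch id.
    """
    h, w = tissue.shape
    labels = np.zeros((h, w), dtype=np.int32)
    target = frac * tissue.sum()
    if target <= 0:
        return labels
    yy, xx = np.mgrid[0:h, 0:w]
    centers = np.argwhere(tissue)
    covered = 0
    k = 0
    while covered < target and k < 64:
        k += 1
        cy, cx = centers[rng.integers(len(centers))]
        r = rng.integers(max(8, min(h, w) // 16), max(12, min(h, w) // 6))
        disk = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r) & tissue
        labels[disk] = k
        covered = (labels > 0).sum()
    return labels


def _paint_nuclei(rng: np.random.Generator, img: np.ndarray, tissue: np.ndarray,
                  density: np.ndarray) -> None:
    """Stamp dark disks (radius 2-6 px) so local coverage tracks ``density``.

    density: per-pixel target blob *coverage fraction* in [0, 1].
    """
    h, w = img.shape[:2]
    mean_area = np.pi * np.mean(np.arange(2, 7) ** 2)    # E[pi r^2], r ~ U{2..6}
    weights = np.where(tissue, density, 0.0).ravel()
    total = weights.sum()
    if total <= 0:
        return
    n_blobs = int(round(total / mean_area))
    if n_blobs == 0:
        return
    idx = rng.choice(h * w, size=n_blobs, replace=True, p=weights / total)
    cy, cx = np.divmod(idx, w)
    radii = rng.integers(2, 7, size=n_blobs)
    jitter = rng.normal(0, 10, size=(n_blobs, 3))
    for y, x, r, dj in zip(cy, cx, radii, jitter):
        y0, y1 = max(0, y - r), min(h, y + r + 1)
        x0, x1 = max(0, x - r), min(w, x + r + 1)
        sy, sx = np.mgrid[y0:y1, x0:x1]
        disk = ((sy - y) ** 2 + (sx - x) ** 2 <= r * r) & tissue[y0:y1, x0:x1]
        color = np.clip(NUCLEUS_RGB + dj, 0, 160)
        img[y0:y1, x0:x1][disk] = color


def _render_slide(rng: np.random.Generator, spec: CohortSpec, level_map: np.ndarray,
                  tissue: np.ndarray, density_noise: float, signal: float) -> np.ndarray:
    """Render one slide: white background, pink tissue, nuclei by local level."""
    h, w = tissue.shape
    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = BACKGROUND_MIN + rng.random((h, w, 1)).astype(np.float32) * (255 - BACKGROUND_MIN)
    texture = rng.normal(0, 6, size=(h, w, 1)).astype(np.float32)
    img[tissue] = np.clip(TISSUE_RGB + texture, 100, 255)[tissue]
    # coverage in [0.03, 0.53]: monotone in signal * level/100, slide-level noise
    drive = np.clip(signal * level_map / 100.0 + density_noise, 0.0, 1.0)
    coverage = 0.03 + 0.5 * drive
    _paint_nuclei(rng, img, tissue, coverage)
    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    # background must satisfy the whiteness rule exactly (all channels >= 220)
    out[~tissue] = np.maximum(out[~tissue], BACKGROUND_MIN)
    return out


def generate_cohort(spec: CohortSpec) -> tuple[list[SlideRecord], pd.DataFrame]:
    """Generate a deterministic synthetic cohort.

    Returns the slide records (with validation-only ``truth_map``) and the
    trait table with one row per slide. The bulk value of the driving trait
    equals the tissue-area mean of the slide's truth_map.
    """
    rng = np.random.default_rng(spec.seed)
    n_slides = spec.n_patients * spec.timepoints_per_patient
    driver = spec.trait_specs[0]
    if driver.kind != "continuous":
        raise ValueError("the first (density-driving) trait must be continuous")

    base_levels = rng.uniform(0, 100, size=n_slides)
    density_noise = rng.normal(0, driver.noise_sd, size=n_slides)

    records: list[SlideRecord] = []
    h, w = spec.image_height, spec.image_width
    slide_idx = 0
    for p in range(spec.n_patients):
        patient_id = f"P{p:03d}"
        for t in range(spec.timepoints_per_patient):
            slide_rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 7, slide_idx]))
            tissue = _tissue_mask(slide_rng, h, w, spec.background_fraction)
            patches = _patch_labels(slide_rng, tissue,
                                    spec.heterogeneity_patch_fraction)
            level_map = np.full((h, w), base_levels[slide_idx], dtype=np.float32)
            for k in range(1, patches.max() + 1):
                level_map[patches == k] = slide_rng.uniform(0, 100)
            level_map[~tissue] = 0.0
            img = _render_slide(slide_rng, spec, level_map, tissue,
                                density_noise[slide_idx], driver.signal_strength)
            bulk = float(level_map[tissue].mean()) if tissue.any() else 0.0
            records.append(SlideRecord(
                slide_id=f"S{slide_idx:03d}", patient_id=patient_id, timepoint=t,
                image=img, traits={driver.name: bulk}, truth_map=level_map))
            slide_idx += 1

    bulk_driver = np.array([r.traits[driver.name] for r in records])
    for ts in spec.trait_specs[1:]:
        z = ts.signal_strength * (bulk_driver / 100.0) + \
            ts.noise_sd * rng.normal(size=n_slides)
        if ts.kind == "continuous":
            # rank-map to a uniform grid on (0, 100)
            ranks = np.argsort(np.argsort(z, kind="stable"), kind="stable")
            values = 100.0 * (ranks + 1) / (n_slides + 1)
        else:
            values = (z > np.median(z)).astype(float)
        for r, v in zip(records, values):
            r.traits[ts.name] = float(v)

    table = pd.DataFrame([
        {"slide_id": r.slide_id, "patient_id": r.patient_id,
         "timepoint": r.timepoint, **r.traits}
        for r in records])
    return records, table


def write_cohort(records: list[SlideRecord], table: pd.DataFrame,
                 out_dir: str | Path) -> Path:
    """Write slides as PNG, truth maps as float32 TIFF sidecars, traits as CSV.

    Round-trips losslessly through :func:`hetile.tiling.read_cohort`.
    """
    if not records:
        raise ValueError("no records to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for r in records:
        Image.fromarray(r.image).save(out / f"{r.slide_id}.png")
        if r.truth_map is not None:
            tifffile.imwrite(out / "truth" / f"{r.slide_id}_truth.tif",
                             r.truth_map.astype(np.float32))
    table.to_csv(out / "traits.csv", index=False, float_format="%.12g")
    return out


def mean_tissue_darkness(image: np.ndarray, whiteness_threshold: int = 220) -> float:
    """Mean (255 - channel mean) over non-background pixels; the density readout."""
    background = (image >= whiteness_threshold).all(axis=-1)
    tissue = ~background
    if not tissue.any():
        return 0.0
    return float((255.0 - image[tissue].mean(axis=-1)).mean())
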