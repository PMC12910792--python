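"""Synthetic fluorescence tissue fields with ground-truth condensate labels.

The generator emulates the image structure the downstream analysis assumes:
round nuclei scattered over a tissue field at a chosen density, each hosting
a number of bright sub-nuclear condensates; optics add Gaussian blur and a
smooth uneven background; the camera adds shot (Poisson) and read (Gaussian)
noise.  Two-group cohorts model a knockout-vs-wildtype comparison in which
the knockout carries more and smaller condensates.

Condensates are circular disks placed before any blur, so each object's true
area is unambiguous: the pixel count of its rasterized disk times the squared
pixel size.  Ground truth (label map + object table) always reflects this
pre-blur geometry.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import Plane, ZStack

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "CohortDataset",
    "sparse_preset",
    "dense_preset",
    "knockout_variant",
    "generate_plane",
    "generate_stack",
    "generate_cohort",
    "sample_ground_truth_areas",
    "cohort_truth_areas",
]


# ---------------------------------------------------------------- spec


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic tissue field.

    Lengths are µm unless the name says px.  ``nucleus_density`` is nuclei
    per 100×100 µm of field.  Condensate counts per nucleus follow a
    distribution selected by ``condensates_per_nucleus_dispersion`` (the
    variance-to-mean ratio): 0 gives the deterministic count
    ``round(mean)``, 1 gives Poisson, >1 a negative binomial with that
    overdispersion.  Condensate areas in µm² are log-normal with the given
    log-mean and log-sd; ``condensate_min_separation_um`` enforces an
    extra edge-to-edge gap between condensates within a nucleus (0 allows
    touching disks, which merge under blur — the realistic hard case).
    Noise is Poisson at ``noise_gain`` photons per intensity unit (0
    disables shot noise) followed by additive Gaussian read noise.
    """

    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.173
    nucleus_density: float = 12.0
    nucleus_radius_um: float = 3.5
    nucleus_radius_jitter_um: float = 0.5
    condensates_per_nucleus_mean: float = 6.0
    condensates_per_nucleus_dispersion: float = 1.5
    condensate_area_log_mean: float = math.log(2.0)
    condensate_area_log_sd: float = 0.5
    condensate_min_separation_um: float = 0.0
    condensate_peak_intensity: float = 300.0
    nucleus_intensity: float = 60.0
    background_level: float = 100.0
    background_gradient: tuple[float, float] = (0.02, 0.01)
    psf_sigma_um: float = 0.2
    noise_gain: float = 1.0
    read_noise_sd: float = 5.0
    n_z_slices: int = 1
    defocus_sigma_per_slice_um: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_size_px
        if h <= 0 or w <= 0:
            raise ValueError("field_size_px entries must be positive")
        for name in ("pixel_size_um", "nucleus_radius_um"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")
        for name in (
            "nucleus_density",
            "nucleus_radius_jitter_um",
            "condensates_per_nucleus_mean",
            "condensates_per_nucleus_dispersion",
            "condensate_area_log_sd",
            "condensate_min_separation_um",
            "background_level",
            "psf_sigma_um",
            "noise_gain",
            "read_noise_sd",
            "defocus_sigma_per_slice_um",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_z_slices < 1:
            raise ValueError("n_z_slices must be >= 1")

    def replace(self, **changes) -> "SyntheticSpec":
        return dataclasses.replace(self, **changes)


def sparse_preset(**overrides) -> SyntheticSpec:
    """Sparse tissue regime (cerebellum-like fields): well separated nuclei."""
    return SyntheticSpec(**overrides)


def dense_preset(**overrides) -> SyntheticSpec:
    """Dense tissue regime (hippocampus-like): crowded nuclei, a stress test
    for false-positive rejection."""
    defaults = dict(nucleus_density=40.0, nucleus_radius_um=2.8, nucleus_radius_jitter_um=0.3)
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


def knockout_variant(
    spec: SyntheticSpec,
    count_factor: float = 1.4,
    log_mean_factor: float = 0.7,
) -> SyntheticSpec:
    """Knockout-like counterpart of a spec: more condensates per nucleus
    (count mean ×1.4) shifted toward smaller areas (log-mean ×0.7)."""
    return spec.replace(
        condensates_per_nucleus_mean=spec.condensates_per_nucleus_mean * count_factor,
        condensate_area_log_mean=spec.condensate_area_log_mean * log_mean_factor,
    )


# ---------------------------------------------------------------- ground truth


@dataclass(frozen=True)
class GroundTruth:
    """Pre-blur geometry of one synthetic field.

    ``label_map`` holds 0 for background and k for condensate k, labels
    consecutive from 1.  ``objects`` has one row per condensate with its
    id, true area in µm² (pixel count × pixel size²), centroid (row, col)
    and host nucleus id.  ``nucleus_mask`` marks all nuclear pixels.
    """

    label_map: np.ndarray
    objects: pd.DataFrame
    nucleus_mask: np.ndarray

    @property
    def n_objects(self) -> int:
        return len(self.objects)


_OBJECT_COLUMNS = ["id", "area_um2", "centroid_row", "centroid_col", "nucleus_id"]


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion == 0:
        return int(round(mean))
    if dispersion <= 1.0:
        return int(rng.poisson(mean))
    # negative binomial parameterized by mean and variance = dispersion * mean
    p = 1.0 / dispersion
    n = mean * p / (1.0 - p)
    return int(rng.negative_binomial(n, p))


def _disk_pixels(cy: float, cx: float, r_px: float, shape: tuple[int, int]):
    """Integer pixel coordinates whose centers lie within the disk."""
    r_ceil = int(math.ceil(r_px))
    y0, y1 = int(math.floor(cy)) - r_ceil, int(math.ceil(cy)) + r_ceil + 1
    x0, x1 = int(math.floor(cx)) - r_ceil, int(math.ceil(cx)) + r_ceil + 1
    y0, x0 = max(y0, 0), max(x0, 0)
    y1, x1 = min(y1, shape[0]), min(x1, shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    return yy[inside], xx[inside]


@dataclass
class _Scene:
    nuclei: list  # (cy, cx, r_px)
    condensates: list  # (cy, cx, r_px, nucleus_id)
    shortfall: int


_MAX_NUCLEUS_ATTEMPTS = 200
_MAX_CONDENSATE_ATTEMPTS = 60


def _sample_scene(spec: SyntheticSpec, rng: np.random.Generator) -> _Scene:
    h, w = spec.field_size_px
    ps = spec.pixel_size_um
    field_area_um2 = h * w * ps * ps
    n_nuclei = int(round(spec.nucleus_density * field_area_um2 / 1e4))

    nuclei: list[tuple[float, float, float]] = []
    for _ in range(n_nuclei):
        placed = False
        for _ in range(_MAX_NUCLEUS_ATTEMPTS):
            r_um = spec.nucleus_radius_um + rng.uniform(
                -spec.nucleus_radius_jitter_um, spec.nucleus_radius_jitter_um
            )
            r_px = max(r_um, 0.5) / ps
            if 2 * r_px >= min(h, w):
                continue  # field cannot hold this nucleus
            cy = rng.uniform(r_px, h - r_px)
            cx = rng.uniform(r_px, w - r_px)
            if all((cy - ny) ** 2 + (cx - nx) ** 2 > (r_px + nr) ** 2 for ny, nx, nr in nuclei):
                nuclei.append((cy, cx, r_px))
                placed = True
                break
        if not placed:
            logger.debug("nucleus placement shortfall (density too high for field)")

    condensates: list[tuple[float, float, float, int]] = []
    shortfall = 0
    gap_px = spec.condensate_min_separation_um / ps
    for nucleus_id, (ny, nx, nr) in enumerate(nuclei, start=1):
        count = _draw_count(
            rng, spec.condensates_per_nucleus_mean, spec.condensates_per_nucleus_dispersion
        )
        local: list[tuple[float, float, float]] = []
        for _ in range(count):
            area = rng.lognormal(spec.condensate_area_log_mean, spec.condensate_area_log_sd)
            r_px = math.sqrt(area / math.pi) / ps
            placed = False
            if r_px < nr:
                for _ in range(_MAX_CONDENSATE_ATTEMPTS):
                    # uniform in the disk of allowed centers
                    rho = (nr - r_px) * math.sqrt(rng.uniform())
                    theta = rng.uniform(0, 2 * math.pi)
                    cy = ny + rho * math.sin(theta)
                    cx = nx + rho * math.cos(theta)
                    if all(
                        (cy - oy) ** 2 + (cx - ox) ** 2 > (r_px + orr + gap_px) ** 2
                        for oy, ox, orr in local
                    ):
                        local.append((cy, cx, r_px))
                        condensates.append((cy, cx, r_px, nucleus_id))
                        placed = True
                        break
            if not placed:
                shortfall += 1
    if shortfall:
        logger.debug("condensate placement shortfall: %d objects dropped", shortfall)
    return _Scene(nuclei=nuclei, condensates=condensates, shortfall=shortfall)


def _ground_truth(spec: SyntheticSpec, scene: _Scene) -> GroundTruth:
    h, w = spec.field_size_px
    ps2 = spec.pixel_size_um**2
    label_map = np.zeros((h, w), dtype=np.int32)
    nucleus_mask = np.zeros((h, w), dtype=bool)
    for ny, nx, nr in scene.nuclei:
        yy, xx = _disk_pixels(ny, nx, nr, (h, w))
        nucleus_mask[yy, xx] = True
    rows = []
    for k, (cy, cx, r_px, nucleus_id) in enumerate(scene.condensates, start=1):
        yy, xx = _disk_pixels(cy, cx, r_px, (h, w))
        label_map[yy, xx] = k
        rows.append((k, len(yy) * ps2, cy, cx, nucleus_id))
    objects = pd.DataFrame(rows, columns=_OBJECT_COLUMNS)
    return GroundTruth(label_map=label_map, objects=objects, nucleus_mask=nucleus_mask)


def _ideal_signal(spec: SyntheticSpec, scene: _Scene, truth: GroundTruth) -> np.ndarray:
    """Pre-blur foreground signal: nuclei plus condensate peaks, no background."""
    signal = np.zeros(spec.field_size_px, dtype=np.float64)
    signal[truth.nucleus_mask] = spec.nucleus_intensity
    signal[truth.label_map > 0] += spec.condensate_peak_intensity
    return signal


def _background(spec: SyntheticSpec) -> np.ndarray:
    h, w = spec.field_size_px
    gy, gx = spec.background_gradient
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    return spec.background_level + gy * rows + gx * cols


def _apply_noise(img: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    out = img
    if spec.noise_gain > 0:
        out = rng.poisson(np.maximum(out, 0.0) * spec.noise_gain) / spec.noise_gain
    if spec.read_noise_sd > 0:
        out = out + rng.normal(0.0, spec.read_noise_sd, size=out.shape)
    return np.asarray(out, dtype=np.float64)


# ---------------------------------------------------------------- generation


def generate_stack(spec: SyntheticSpec) -> tuple[ZStack, GroundTruth]:
    """Simulate a Z-stack of one field.

    One in-focus scene is generated; slice z is additionally blurred by
    ``defocus_sigma_per_slice_um * |z - z_focus(x, y)|`` where the focal
    surface z_focus ramps linearly across the field width, so different
    field regions are sharpest in different slices.  Noise is drawn
    independently per slice.
    """
    rng = np.random.default_rng(spec.seed)
    scene = _sample_scene(spec, rng)
    truth = _ground_truth(spec, scene)

    psf_px = spec.psf_sigma_um / spec.pixel_size_um
    in_focus = _ideal_signal(spec, scene, truth)
    if psf_px > 0:
        in_focus = ndimage.gaussian_filter(in_focus, psf_px, mode="reflect")

    h, w = spec.field_size_px
    nz = spec.n_z_slices
    defocus_px = spec.defocus_sigma_per_slice_um / spec.pixel_size_um
    background = _background(spec)

    if nz == 1 or defocus_px == 0:
        slices = []
        for _z in range(nz):
            slices.append(_apply_noise(in_focus + background, spec, rng))
        return ZStack(np.stack(slices), spec.pixel_size_um), truth

    # focal surface: z_focus ramps 0 -> nz-1 across columns
    cols = np.arange(w, dtype=np.float64)
    z_focus = np.broadcast_to((nz - 1) * cols / max(w - 1, 1), (h, w))

    # bank of uniformly defocused scenes at integer defocus steps
    bank = [in_focus]
    for j in range(1, nz):
        bank.append(ndimage.gaussian_filter(in_focus, defocus_px * j, mode="reflect"))
    bank_arr = np.stack(bank)

    slices = []
    for z in range(nz):
        d = np.abs(z - z_focus)  # in [0, nz-1]
        lo = np.floor(d).astype(int)
        hi = np.minimum(lo + 1, nz - 1)
        frac = d - lo
        sharp = (
            np.take_along_axis(bank_arr, lo[None], axis=0)[0] * (1 - frac)
            + np.take_along_axis(bank_arr, hi[None], axis=0)[0] * frac
        )
        slices.append(_apply_noise(sharp + background, spec, rng))
    return ZStack(np.stack(slices), spec.pixel_size_um), truth


def generate_plane(spec: SyntheticSpec) -> tuple[Plane, GroundTruth]:
    """Simulate a single in-focus field (the 1-slice special case of
    :func:`generate_stack`, bit-identical to its only slice)."""
    stack, truth = generate_stack(spec.replace(n_z_slices=1))
    return stack.slice(0), truth


@dataclass(frozen=True)
class CohortDataset:
    """A two-group synthetic cohort: one image (plane or stack) and its
    ground truth per subject, plus a metadata table (subject_id, group,
    seed)."""

    images: list
    truths: list[GroundTruth]
    metadata: pd.DataFrame


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def generate_cohort(
    spec_group_a: SyntheticSpec,
    spec_group_b: SyntheticSpec,
    n_per_group: int,
    seed: int,
    group_names: tuple[str, str] = ("WT", "KO"),
) -> CohortDataset:
    """Simulate ``n_per_group`` fields per group with per-field derived seeds."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    seeds = _derive_seeds(seed, 2 * n_per_group)
    images, truths, meta = [], [], []
    for i, s in enumerate(seeds):
        group = group_names[0] if i < n_per_group else group_names[1]
        spec = (spec_group_a if i < n_per_group else spec_group_b).replace(seed=s)
        if spec.n_z_slices > 1:
            img, truth = generate_stack(spec)
        else:
            img, truth = generate_plane(spec)
        images.append(img)
        truths.append(truth)
        meta.append((f"{group}_{i % n_per_group + 1:02d}", group, s))
    metadata = pd.DataFrame(meta, columns=["subject_id", "group", "seed"])
    return CohortDataset(images=images, truths=truths, metadata=metadata)


# ------------------------------------------------- fast ground-truth sampling


def sample_ground_truth_areas(spec: SyntheticSpec) -> np.ndarray:
    """True condensate areas (µm²) of one field, without rendering the image.

    Draws the same geometry as :func:`generate_plane` (identical rng
    consumption for the scene) but skips rasterizing intensities, for
    Monte-Carlo studies over ground truth alone.
    """
    rng = np.random.default_rng(spec.seed)
    scene = _sample_scene(spec, rng)
    ps2 = spec.pixel_size_um**2
    areas = []
    for cy, cx, r_px, _nid in scene.condensates:
        yy, _xx = _disk_pixels(cy, cx, r_px, spec.field_size_px)
        areas.append(len(yy) * ps2)
    return np.asarray(areas, dtype=np.float64)


def cohort_truth_areas(
    spec_group_a: SyntheticSpec,
    spec_group_b: SyntheticSpec,
    n_per_group: int,
    seed: int,
    group_names: tuple[str, str] = ("WT", "KO"),
) -> pd.DataFrame:
    """Per-subject true-area table for a cohort (subject_id, group, area_um2),
    ground truth only — the fast path for replicate statistical studies."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    seeds = _derive_seeds(seed, 2 * n_per_group)
    frames = []
    for i, s in enumerate(seeds):
        group = group_names[0] if i < n_per_group else group_names[1]
        spec = (spec_group_a if i < n_per_group else spec_group_b).replace(seed=s)
        areas = sample_ground_truth_areas(spec)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": f"{group}_{i % n_per_group + 1:02d}",
                    "group": group,
                    "area_um2": areas,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
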