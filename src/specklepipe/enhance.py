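"""Signal conditioning before segmentation.

Two classical steps, applied in sequence: rolling-ball background
subtraction (grayscale opening by a spherical-cap structuring element, the
Sternberg construction, with the cap height scale equal to its radius in
pixels) removes the smooth background, then a difference-of-Gaussians
band-pass isolates blob-like structure between the two sigma scales.
Defaults are radius 10 px and sigmas 2 / 10 px.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import Plane

__all__ = [
    "EnhanceParams",
    "rolling_ball_subtract",
    "difference_of_gaussians",
    "enhance",
]


@dataclass(frozen=True)
class EnhanceParams:
    rolling_ball_radius_px: float = 10.0
    dog_sigma_low_px: float = 2.0
    dog_sigma_high_px: float = 10.0
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if self.rolling_ball_radius_px < 1:
            raise ValueError("rolling_ball_radius_px must be >= 1")
        if not (0 < self.dog_sigma_low_px < self.dog_sigma_high_px):
            raise ValueError("require 0 < dog_sigma_low_px < dog_sigma_high_px")


def _ball_structure(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Spherical-cap structuring function: height sqrt(r² − d²) on the disk
    of radius r (footprint), so the cap's height scale equals its radius."""
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = yy * yy + xx * xx
    footprint = d2 <= radius * radius
    height = np.where(footprint, np.sqrt(np.maximum(radius * radius - d2, 0.0)), 0.0)
    return height, footprint


def rolling_ball_subtract(plane: Plane, radius_px: float) -> Plane:
    """Subtract the rolling-ball background estimate.

    The background is the grayscale opening (erosion then dilation) of the
    image by the ball structuring element; the result ``image − background``
    is nonnegative and pointwise ≤ the input.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    data = np.asarray(plane.data, dtype=np.float64)
    height, footprint = _ball_structure(radius_px)
    background = ndimage.grey_opening(
        data, structure=height, footprint=footprint, mode="nearest"
    )
    return plane.with_data(np.clip(data - background, 0.0, None))


def difference_of_gaussians(
    plane: Plane,
    sigma_low: float,
    sigma_high: float,
    clip_negative: bool = True,
) -> Plane:
    """Band-pass: G(σ_low)∗image − G(σ_high)∗image, reflective boundaries,
    kernels truncated at 4σ.  Negative response is clipped by default since
    only bright foci are sought."""
    if not (0 < sigma_low < sigma_high):
        raise ValueError("require 0 < sigma_low < sigma_high")
    data = np.asarray(plane.data, dtype=np.float64)
    low = ndimage.gaussian_filter(data, sigma_low, mode="reflect", truncate=4.0)
    high = ndimage.gaussian_filter(data, sigma_high, mode="reflect", truncate=4.0)
    out = low - high
    if clip_negative:
        out = np.clip(out, 0.0, None)
    return plane.with_data(out)


def enhance(plane: Plane, params: EnhanceParams = EnhanceParams()) -> Plane:
    """Rolling-ball subtraction followed by difference of Gaussians."""
    subtracted = rolling_ball_subtract(plane, params.rolling_ball_radius_px)
    return difference_of_gaussians(
        subtracted,
        params.dog_sigma_low_px,
        params.dog_sigma_high_px,
        clip_negative=params.clip_negative,
    )
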