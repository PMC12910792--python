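"""Extended depth of field (EDF) by the local-variance method.

A Z-stack is collapsed to one all-in-focus plane: for each pixel the slice
with the highest local intensity variance (the sharpest slice at that
location) is selected, the selection map is median-smoothed, and the output
pixel is a weighted blend of the selected slice with its z-neighbours.

The three blend parameters keep the roles they have in acquisition
software: ``contrast_length`` is the blend depth in slices on either side,
``smoothing`` the half-width of the median filter applied to the slice
index map, and ``reconstruction_factor`` the per-step decay of the
neighbour weights (0 = pure slice selection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import Plane, ZStack

__all__ = ["EdfParams", "local_variance", "edf_variance", "SPARSE_EDF", "DENSE_EDF"]


@dataclass(frozen=True)
class EdfParams:
    window_radius_px: int = 4
    smoothing: int = 5
    contrast_length: int = 3
    reconstruction_factor: float = 0.05
    align_stack: bool = False

    def __post_init__(self) -> None:
        if self.window_radius_px < 1:
            raise ValueError("window_radius_px must be >= 1")
        if self.smoothing < 0:
            raise ValueError("smoothing must be nonnegative")
        if self.contrast_length < 1:
            raise ValueError("contrast_length must be >= 1")
        if not (0.0 <= self.reconstruction_factor <= 1.0):
            raise ValueError("reconstruction_factor must be in [0, 1]")


#: presets mirroring the two acquisition regimes
SPARSE_EDF = EdfParams(contrast_length=3, smoothing=5, reconstruction_factor=0.05)
DENSE_EDF = EdfParams(contrast_length=3, smoothing=2, reconstruction_factor=0.01)


def local_variance(plane: Plane, window_radius_px: int) -> np.ndarray:
    """Population variance of intensities in the (2r+1)² window around each
    pixel, with reflective (symmetric) boundary padding."""
    if window_radius_px < 1:
        raise ValueError("window_radius_px must be >= 1")
    data = np.asarray(plane.data, dtype=np.float64)
    size = 2 * window_radius_px + 1
    mean = ndimage.uniform_filter(data, size=size, mode="reflect")
    mean_sq = ndimage.uniform_filter(data * data, size=size, mode="reflect")
    return np.maximum(mean_sq - mean * mean, 0.0)


def edf_variance(stack: ZStack, params: EdfParams) -> tuple[Plane, np.ndarray]:
    """Collapse a stack to an all-in-focus plane.

    Returns the EDF plane and the (median-smoothed) slice index map.
    Ties in the per-pixel variance argmax resolve to the lowest slice
    index; with ``reconstruction_factor`` 0 the output is pure per-pixel
    slice selection.
    """
    if params.align_stack:
        raise ValueError("Z-stack alignment is not supported; set align_stack=False")
    nz = stack.n_slices
    if nz == 0:
        raise ValueError("empty stack")
    data = np.asarray(stack.data, dtype=np.float64)

    if nz == 1:
        return stack.slice(0), np.zeros(data.shape[1:], dtype=np.int32)

    var = np.stack(
        [local_variance(stack.slice(z), params.window_radius_px) for z in range(nz)]
    )
    index_map = np.argmax(var, axis=0).astype(np.int32)  # first max = lowest z

    if params.smoothing > 0:
        index_map = ndimage.median_filter(
            index_map, size=2 * params.smoothing + 1, mode="reflect"
        ).astype(np.int32)

    L = params.contrast_length
    f = params.reconstruction_factor
    weight_sum = np.zeros(index_map.shape, dtype=np.float64)
    blend = np.zeros(index_map.shape, dtype=np.float64)
    for dz in range(-L, L + 1):
        w = 1.0 if dz == 0 else f ** abs(dz)
        if w == 0.0:
            continue
        idx = index_map + dz
        valid = (idx >= 0) & (idx < nz)
        idx_c = np.clip(idx, 0, nz - 1)
        vals = np.take_along_axis(data, idx_c[None], axis=0)[0]
        blend += np.where(valid, w * vals, 0.0)
        weight_sum += np.where(valid, w, 0.0)
    out = blend / weight_sum
    return Plane(out, pixel_size_um=stack.pixel_size_um), index_map
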