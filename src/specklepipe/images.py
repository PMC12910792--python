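"""Calibrated image containers and TIFF I/O.

Every image operation in the pipeline works on a :class:`Plane` (single
2-D grayscale image) or a :class:`ZStack` (ordered set of planes), both
carrying their physical calibration in µm/pixel.  Object areas in µm²
are always ``pixel_count * pixel_size_um**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["Plane", "ZStack", "RegionOfInterest", "read_image", "write_plane", "write_stack"]


@dataclass(frozen=True)
class Plane:
    """A single calibrated grayscale image.

    Parameters
    ----------
    data : ndarray, shape (H, W)
        Pixel intensities. Kept in whatever dtype the producer used;
        intermediates are float, acquisitions 16-bit.
    pixel_size_um : float
        Physical pixel size in µm/pixel. Must be positive.
    """

    data: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 2:
            raise ValueError(f"Plane data must be 2-D, got shape {d.shape}")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "data", d)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Plane":
        """Same calibration, new pixel values."""
        return Plane(data=data, pixel_size_um=self.pixel_size_um)


@dataclass(frozen=True)
class ZStack:
    """An ordered stack of planes sharing one calibration.

    ``data`` has shape (Z, H, W) with slice 0 first acquired.
    """

    data: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3 or d.shape[0] < 1:
            raise ValueError(f"ZStack data must be 3-D (Z, H, W) with Z >= 1, got {d.shape}")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "data", d)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def slice(self, z: int) -> Plane:
        return Plane(data=self.data[z], pixel_size_um=self.pixel_size_um)


@dataclass(frozen=True)
class RegionOfInterest:
    """Named binary mask restricting detection and measurement."""

    name: str
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        object.__setattr__(self, "mask", m.astype(bool))

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def full_field(cls, shape: tuple[int, int], name: str = "full_field") -> "RegionOfInterest":
        return cls(name=name, mask=np.ones(shape, dtype=bool))


def read_image(path, pixel_size_um: float):
    """Read a TIFF as a Plane (single page) or ZStack (multi-page)."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        return Plane(data=data, pixel_size_um=pixel_size_um)
    if data.ndim == 3:
        return ZStack(data=data, pixel_size_um=pixel_size_um)
    raise ValueError(f"unsupported TIFF dimensionality {data.ndim} in {path}")


def write_plane(path, plane: Plane, dtype=None) -> None:
    """Write a single-page TIFF; 16-bit output is clipped to the dtype range."""
    data = plane.data
    if dtype is not None:
        info = np.iinfo(dtype) if np.issubdtype(np.dtype(dtype), np.integer) else None
        if info is not None:
            data = np.clip(np.rint(data), info.min, info.max)
        data = data.astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")


def write_stack(path, stack: ZStack, dtype=None) -> None:
    data = stack.data
    if dtype is not None:
        info = np.iinfo(dtype) if np.issubdtype(np.dtype(dtype), np.integer) else None
        if info is not None:
            data = np.clip(np.rint(data), info.min, info.max)
        data = data.astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
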