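"""Shared data containers: detector grid, portal images and dose planes.

All planar data in this package live on a square pixel grid at the
source-axis-distance (SAD) plane.  The beam axis is taken to pass through
the *central pixel* ``(n // 2, n // 2)`` (0-based), so that pixel's center
has physical coordinate (0 mm, 0 mm).  On an even-sided grid this is the
same single-pixel convention used for the normalization factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "PortalImage",
    "DoseDistribution",
    "GeometryError",
    "flip_about_center",
]


class GeometryError(ValueError):
    """A beam segment is geometrically incompatible with the detector grid."""


@dataclass(frozen=True)
class GridSpec:
    """Square detector grid expressed at the SAD plane.

    Parameters
    ----------
    n_pixels:
        Pixels per side; must be even and at least 32.
    pixel_pitch:
        Pixel spacing in mm at the SAD plane.
    """

    n_pixels: int
    pixel_pitch: float

    def __post_init__(self) -> None:
        if self.n_pixels < 32 or self.n_pixels % 2 != 0:
            raise ValueError(f"n_pixels must be even and >= 32, got {self.n_pixels}")
        if self.pixel_pitch <= 0:
            raise ValueError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")

    @property
    def side_mm(self) -> float:
        """Physical side length of the grid (mm)."""
        return self.n_pixels * self.pixel_pitch

    @property
    def center_index(self) -> int:
        """0-based index of the beam-axis pixel along either axis."""
        return self.n_pixels // 2

    def coords(self) -> np.ndarray:
        """Pixel-center coordinates (mm) along one axis; 0 at the beam axis."""
        return (np.arange(self.n_pixels) - self.center_index) * self.pixel_pitch

    def radius_map(self) -> np.ndarray:
        """2D map of radial distance (mm) from the beam axis."""
        c = self.coords()
        return np.hypot(c[:, None], c[None, :])


@dataclass
class PortalImage:
    """Flood-field-corrected 16-bit grayscale portal image (mPI)."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        _check_shape(self.values, self.grid)
        if self.values.dtype != np.uint16:
            vmin, vmax = float(self.values.min()), float(self.values.max())
            if vmin < 0 or vmax > 65535:
                raise ValueError("portal image values must lie in [0, 65535]")
            self.values = np.round(self.values).astype(np.uint16)

    @property
    def central_value(self) -> int:
        c = self.grid.center_index
        return int(self.values[c, c])


@dataclass
class DoseDistribution:
    """2D absolute dose plane (Gy) at the SAD plane, 50 mm water depth."""

    values: np.ndarray
    grid: GridSpec
    unit: str = "Gy"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_shape(self.values, self.grid)
        if self.unit != "Gy":
            raise ValueError(f"dose unit must be 'Gy', got {self.unit!r}")

    @property
    def central_value(self) -> float:
        c = self.grid.center_index
        return float(self.values[c, c])


def _check_shape(values: np.ndarray, grid: GridSpec) -> None:
    expected = (grid.n_pixels, grid.n_pixels)
    if values.shape != expected:
        raise ValueError(f"array shape {values.shape} does not match grid {expected}")


def flip_about_center(a: np.ndarray, axis: int) -> np.ndarray:
    """Mirror ``a`` about the central pixel ``n // 2`` along ``axis``.

    On an even-sided grid a plain ``np.flip`` mirrors about the grid
    midpoint (between pixels) and shifts everything by one pixel; this
    helper instead maps index ``c + k`` to ``c - k`` so that beams centered
    on the beam axis map onto themselves.
    """
    return np.roll(np.flip(a, axis=axis), 1, axis=axis)
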