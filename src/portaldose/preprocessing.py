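"""Data conditioning: edge correction, normalization, absolute calibration.

The analytical dose-prediction chain erodes the borders of dose planes for
beams protruding from the detector, so both images and doses are "edge
corrected": a fixed-width border is discarded and refilled by
nearest-neighbor extrapolation from the interior.  Inputs and outputs are
then rescaled by the central pixel values of the 80 mm reference square
(grayscale units for images, Gy for doses); the dose-side factor doubles as
the absolute calibration of inferred maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import DoseDistribution, GridSpec, PortalImage

__all__ = [
    "NormalizationFactors",
    "edge_correct",
    "default_crop_px",
    "compute_norm_factors",
    "normalize",
    "calibrate",
]

_PAPER_CROP_PX = 32
_PAPER_N = 1024


@dataclass(frozen=True)
class NormalizationFactors:
    """Central-pixel scales of the 80 mm square calibration pair."""

    input_factor: float  # grayscale units
    output_factor: float  # Gy

    def __post_init__(self) -> None:
        if self.input_factor <= 0 or self.output_factor <= 0:
            raise ValueError("normalization factors must be > 0")


def default_crop_px(grid: GridSpec) -> int:
    """Border width scaled with resolution to keep the physical ~7.7 mm crop."""
    return max(1, round(_PAPER_CROP_PX * grid.n_pixels / _PAPER_N))


def edge_correct(image: np.ndarray, crop_px: int) -> np.ndarray:
    """Replace a ``crop_px``-wide border by nearest-interior-pixel values.

    The interior is untouched; border pixels take the value of the closest
    interior pixel (corners take the nearest interior corner).  Idempotent.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("edge_correct expects a 2D map")
    if crop_px <= 0:
        warnings.warn("crop_px <= 0: edge correction is a no-op", stacklevel=2)
        return image.copy()
    n_rows, n_cols = image.shape
    if 2 * crop_px >= min(n_rows, n_cols):
        raise ValueError(f"crop_px={crop_px} too large for shape {image.shape}")
    rows = np.clip(np.arange(n_rows), crop_px, n_rows - 1 - crop_px)
    cols = np.clip(np.arange(n_cols), crop_px, n_cols - 1 - crop_px)
    return image[np.ix_(rows, cols)]


def compute_norm_factors(
    cal_mpi_80: PortalImage, cal_ppd_80: DoseDistribution
) -> NormalizationFactors:
    """Normalization factors from the 80 mm square calibration pair.

    The "central pixel" on an even n-sided grid is (n/2, n/2), 0-based.
    """
    if cal_mpi_80.grid != cal_ppd_80.grid:
        raise ValueError("calibration image and dose must share one grid")
    input_factor = float(cal_mpi_80.central_value)
    output_factor = float(cal_ppd_80.central_value)
    if input_factor <= 0 or output_factor <= 0:
        raise ValueError("invalid calibration field: non-positive central pixel")
    return NormalizationFactors(input_factor=input_factor, output_factor=output_factor)


def normalize(values: np.ndarray, factor: float) -> np.ndarray:
    """Divide a map by a positive scale (dimensionless result)."""
    if factor <= 0:
        raise ValueError(f"normalization factor must be > 0, got {factor}")
    return np.asarray(values, dtype=np.float64) / factor


def calibrate(values: np.ndarray, output_factor: float, grid: GridSpec) -> DoseDistribution:
    """Rescale a dimensionless inferred map back to absolute dose (Gy)."""
    if output_factor <= 0:
        raise ValueError(f"output factor must be > 0, got {output_factor}")
    return DoseDistribution(np.asarray(values, dtype=np.float64) * output_factor, grid)
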