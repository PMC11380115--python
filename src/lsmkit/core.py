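"""Shared containers exchanged between the simulator, calibration and
reconstruction stages.

Coordinate conventions used throughout the package:

* arrays are indexed ``(row, col)`` = ``(y, x)``, 0-based;
* ``z`` increases with stage travel; slice ``k`` was acquired at stage
  position ``k * z_step``;
* all lengths are micrometres unless a name says otherwise; angles are
  degrees at the API boundary and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["SkewEstimate", "StackMeta", "ImageStack", "PSF3D", "Volume"]


@dataclass
class SkewEstimate:
    """Lateral image shift per micrometre of stage z-travel.

    ``sx``/``sy`` are in µm of image-plane displacement per µm of stage
    travel, so they are dimensionless slopes.  ``sheet_angle_phi_deg`` is the
    angle between the sheet plane and the sample plane (ideal 45°).
    """

    sx: float
    sy: float = 0.0
    sheet_angle_phi_deg: float = 90.0
    fit_residual_um: float = 0.0
    n_tracks: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.sheet_angle_phi_deg <= 90.0):
            raise ValueError("sheet_angle_phi_deg must lie in (0, 90]")


@dataclass
class StackMeta:
    """Acquisition metadata attached to an :class:`ImageStack`."""

    pixel_size_um: float
    z_step_um: float
    frame_interval_s: float = 1.0
    skew: Optional[SkewEstimate] = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")


@dataclass
class ImageStack:
    """slices × frames × rows × cols of camera counts plus metadata.

    Static acquisitions have a single frame per slice; dynamics movies carry
    one movie (many frames) per slice.
    """

    data: np.ndarray
    meta: StackMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                "ImageStack.data must be 4D (slices, frames, rows, cols); "
                f"got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data[~np.isnan(self.data)])):
            raise ValueError("ImageStack counts must be finite (NaN fill allowed)")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self):
        return self.data.shape


@dataclass
class PSF3D:
    """Separable 3D Gaussian detection kernel (unit sum, odd dimensions)."""

    lateral_fwhm_px: float
    axial_fwhm_slices: float
    kernel: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.ndim != 3:
            raise ValueError("PSF3D kernel must be 3D")
        if any(s % 2 == 0 for s in self.kernel.shape):
            raise ValueError("PSF3D kernel dimensions must be odd")
        if abs(self.kernel.sum() - 1.0) > 1e-9:
            raise ValueError("PSF3D kernel must sum to 1 within 1e-9")
        if np.any(self.kernel < 0):
            raise ValueError("PSF3D kernel must be nonnegative")


@dataclass
class Volume:
    """Voxel grid with its physical scale ``(PI, PI, z_step)`` in µm/voxel.

    ``voxels`` is indexed ``(z, y, x)``; ``physical_scale`` is given in
    ``(x, y, z)`` order to match how the scale is reported downstream.
    """

    voxels: np.ndarray
    physical_scale: tuple

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("Volume voxels must be 3D (z, y, x)")
        if any(s <= 0 for s in self.physical_scale):
            raise ValueError("physical_scale entries must be positive")

    @property
    def physical_extent_um(self) -> tuple:
        nz, ny, nx = self.voxels.shape
        px, py, pz = self.physical_scale
        return (nx * px, ny * py, nz * pz)
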