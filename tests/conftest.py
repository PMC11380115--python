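"""Shared fixtures: synthetic acquisitions with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from lsmkit.core import PSF3D
from lsmkit.reconstruct import build_psf3d
from lsmkit.simulate import (
    AcquisitionGeometry,
    BeadPhantom,
    NoiseModel,
    SheetProfile,
    render_acquisition,
)

NO_NOISE = NoiseModel(kind="none", offset_counts=0.0)


def moment_centroid(frame: np.ndarray):
    """Intensity-weighted centroid (row, col) ignoring NaN."""
    work = np.nan_to_num(np.asarray(frame, dtype=float))
    total = work.sum()
    if total <= 0:
        raise ValueError("empty frame")
    rr, cc = np.mgrid[: work.shape[0], : work.shape[1]]
    return (work * rr).sum() / total, (work * cc).sum() / total


def single_bead_stack(
    sx: float,
    sy: float,
    z_step_um: float,
    pixel_um: float = 0.1625,
    fov_px: int = 96,
    bead_xyz=(6.0, 8.0, 5.0),
    sheet_thickness_um: float = 6.0,
    n_slices: int = 6,
    psf: PSF3D | None = None,
):
    """One bright bead rendered noise-free through a skewed acquisition."""
    geometry = AcquisitionGeometry(
        sheet_angle_phi_deg=66.0,
        z_step_um=z_step_um,
        image_pixel_um=pixel_um,
        fov_px=(fov_px, fov_px),
        skew_per_um=(sx, sy),
    )
    phantom = BeadPhantom(
        positions_um=np.array([bead_xyz]),
        diameters_um=np.array([1.0]),
        brightness_photons=10000.0,
        volume_dims_um=(fov_px * pixel_um, fov_px * pixel_um,
                        (n_slices - 1) * z_step_um + 1e-9),
    )
    sheet = SheetProfile(thickness_um=sheet_thickness_um, width_um=20.0)
    stack = render_acquisition(
        phantom, geometry, sheet, psf3d=psf, noise=NO_NOISE, seed=1,
        n_slices=n_slices,
    )
    return stack, phantom, geometry


@pytest.fixture(scope="session")
def narrow_psf() -> PSF3D:
    return build_psf3d(lateral_fwhm_px=2.9, axial_fwhm_slices=3.0,
                       kernel_dims=(7, 15, 15))
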