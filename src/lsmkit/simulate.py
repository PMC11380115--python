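"""Synthetic acquisition simulator.

Forward model for a stage-scanned, tilted-sheet microscope: fluorescent
bead phantoms in an index-matched gel are illuminated by a Gaussian sheet,
blurred by the detection PSF, laterally offset slice-by-slice by the stage
skew, rasterized onto the camera grid and corrupted by camera noise.  A
second generator produces per-slice movies of point emitters undergoing
Brownian diffusion, emulating fluorescent dextran diffusing through an
agarose hydrogel.  Every downstream stage (calibration, deskew,
deconvolution, fcsSOFI) is testable against the ground truth these
functions return.

All randomness flows from an explicit ``seed`` (or ``numpy.random.Generator``)
argument; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .core import ImageStack, PSF3D, SkewEstimate, StackMeta

__all__ = [
    "AcquisitionGeometry",
    "SheetProfile",
    "BeadPhantom",
    "DiffusionSimSpec",
    "NoiseModel",
    "make_bead_phantom",
    "render_acquisition",
    "simulate_diffusion_movie",
    "add_camera_noise",
    "stokes_einstein_D",
]

BOLTZMANN_J_PER_K = 1.380649e-23


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Geometry of a stage-scanned acquisition.

    ``sheet_angle_phi_deg`` is the angle between the sheet plane and the
    sample plane (ideal 45°, 66° measured on the reference instrument).
    ``skew_per_um`` = (sx, sy) is the lateral image shift in µm per µm of
    stage z-travel; when derived from the sheet angle, sx = tan(90° − φ).
    """

    sheet_angle_phi_deg: float
    z_step_um: float
    image_pixel_um: float
    fov_px: tuple  # (n_cols, n_rows)
    skew_per_um: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.sheet_angle_phi_deg <= 90.0):
            raise ValueError("sheet_angle_phi_deg must lie in (0, 90]")
        if self.z_step_um <= 0 or self.image_pixel_um <= 0:
            raise ValueError("z_step_um and image_pixel_um must be positive")
        if any(int(v) <= 0 for v in self.fov_px):
            raise ValueError("fov_px entries must be positive")

    @classmethod
    def from_sheet_angle(
        cls,
        sheet_angle_phi_deg: float,
        z_step_um: float,
        image_pixel_um: float,
        fov_px: tuple,
    ) -> "AcquisitionGeometry":
        """Derive the x-skew from the sheet angle: sx = tan(90° − φ), sy = 0."""
        sx = math.tan(math.radians(90.0 - sheet_angle_phi_deg))
        return cls(sheet_angle_phi_deg, z_step_um, image_pixel_um, fov_px, (sx, 0.0))

    @property
    def fov_um(self) -> tuple:
        return (self.fov_px[0] * self.image_pixel_um, self.fov_px[1] * self.image_pixel_um)


@dataclass(frozen=True)
class SheetProfile:
    """Gaussian sheet cross-section.

    ``thickness_um`` is the full 1/e² width across the sheet normal; the
    axial excitation weight is exp(−2 d²/ω²) with ω = thickness/2, so an
    emitter in the sheet plane (d = 0) is excited with weight 1.
    """

    thickness_um: float
    width_um: float

    def __post_init__(self) -> None:
        if self.thickness_um <= 0 or self.width_um <= 0:
            raise ValueError("sheet dimensions must be positive")

    def axial_weight(self, distance_um):
        omega = self.thickness_um / 2.0
        d = np.asarray(distance_um, dtype=float)
        return np.exp(-2.0 * d**2 / omega**2)


@dataclass
class BeadPhantom:
    """Fluorescent beads suspended in an index-matched gel."""

    positions_um: np.ndarray  # (n, 3) of (x, y, z)
    diameters_um: np.ndarray  # (n,)
    brightness_photons: float  # expected photons/frame of a fully excited bead
    volume_dims_um: tuple  # (X, Y, Z)

    def __post_init__(self) -> None:
        self.positions_um = np.atleast_2d(np.asarray(self.positions_um, dtype=float))
        if self.positions_um.size == 0:
            self.positions_um = self.positions_um.reshape(0, 3)
        self.diameters_um = np.asarray(self.diameters_um, dtype=float)
        if self.positions_um.shape[1] != 3:
            raise ValueError("positions_um must be (n, 3)")
        if np.any(self.diameters_um <= 0):
            raise ValueError("diameters must be positive")
        dims = np.asarray(self.volume_dims_um, dtype=float)
        if self.positions_um.shape[0] and (
            np.any(self.positions_um < 0) or np.any(self.positions_um > dims)
        ):
            raise ValueError("bead positions must lie inside volume_dims_um")

    @property
    def n_beads(self) -> int:
        return self.positions_um.shape[0]


@dataclass(frozen=True)
class DiffusionSimSpec:
    """Conditions of a Brownian-diffusion movie."""

    n_walkers: int
    diffusion_um2_per_s: float
    frame_interval_s: float
    n_frames: int
    brightness_photons: float = 300.0
    region_mask: Optional[np.ndarray] = None  # True = accessible, FOV grid
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diffusion_um2_per_s < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_walkers < 0:
            raise ValueError("n_walkers must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise description.

    ``scmos``: Poisson shot noise + Gaussian read noise + offset.
    ``emccd``: Poisson photons amplified by a Gamma-distributed EM register
    (mean gain ``em_gain``, excess noise factor √2) + read noise + offset.
    ``none``: pass-through plus offset.
    """

    kind: Literal["none", "scmos", "emccd"] = "none"
    read_noise_e: float = 2.0
    offset_counts: float = 100.0
    em_gain: float = 1.0
    excess_noise_factor: float = math.sqrt(2.0)

    def __post_init__(self) -> None:
        if self.kind not in ("none", "scmos", "emccd"):
            raise ValueError("kind must be 'none', 'scmos' or 'emccd'")
        if self.read_noise_e < 0:
            raise ValueError("read_noise_e must be >= 0")
        if self.em_gain < 1:
            raise ValueError("em_gain must be >= 1")


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

def make_bead_phantom(
    n: int,
    diameter_mean_um: float,
    diameter_sd_um: float,
    volume_dims_um: tuple,
    brightness_photons: float = 2000.0,
    seed=0,
) -> BeadPhantom:
    """Uniformly random bead positions in the volume with truncated-normal
    (> 0) diameters; reproducible under a fixed seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(seed)
    dims = np.asarray(volume_dims_um, dtype=float)
    positions = rng.uniform(0.0, 1.0, size=(n, 3)) * dims
    diameters = np.empty(n)
    remaining = np.arange(n)
    while remaining.size:  # rejection sampling of the truncated normal
        draw = rng.normal(diameter_mean_um, diameter_sd_um, size=remaining.size)
        good = draw > 0
        diameters[remaining[good]] = draw[good]
        remaining = remaining[~good]
    return BeadPhantom(positions, diameters, brightness_photons, tuple(dims))


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _render_spots(
    shape_rc: tuple,
    x_px: np.ndarray,
    y_px: np.ndarray,
    sigma_px: np.ndarray,
    photons: np.ndarray,
    supersample: int = 4,
) -> np.ndarray:
    """Render Gaussian spots by ``supersample``× area sampling then binning.

    Each spot integrates (over the full plane) to its photon budget; spots
    are evaluated on a local window of ±5σ for speed.
    """
    rows, cols = shape_rc
    s = supersample
    img = np.zeros((rows * s, cols * s))
    # supersampled grid: cell centers at (i + 0.5)/s in pixel units
    for xp, yp, sig, amp in zip(x_px, y_px, sigma_px, photons):
        if amp <= 0:
            continue
        half = 5.0 * sig + 1.0
        r0 = max(int((yp - half) * s), 0)
        r1 = min(int((yp + half) * s) + 1, rows * s)
        c0 = max(int((xp - half) * s), 0)
        c1 = min(int((xp + half) * s) + 1, cols * s)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = (np.arange(r0, r1) + 0.5) / s
        xx = (np.arange(c0, c1) + 0.5) / s
        gy = np.exp(-((yy - yp) ** 2) / (2.0 * sig**2))
        gx = np.exp(-((xx - xp) ** 2) / (2.0 * sig**2))
        norm = amp / (2.0 * math.pi * sig**2 * s**2)
        img[r0:r1, c0:c1] += norm * np.outer(gy, gx)
    # area binning back to the camera grid
    return img.reshape(rows, s, cols, s).sum(axis=(1, 3))


def render_acquisition(
    phantom: BeadPhantom,
    geometry: AcquisitionGeometry,
    sheet: SheetProfile,
    psf3d: Optional[PSF3D] = None,
    exposure_frames: int = 1,
    noise: NoiseModel = NoiseModel(kind="none", offset_counts=0.0),
    seed=0,
    n_slices: Optional[int] = None,
    supersample: int = 4,
) -> ImageStack:
    """Render a bead phantom into a stage-scanned z-stack.

    At stage position ``k * z_step`` each bead is excited with the sheet's
    Gaussian axial weight at its distance from the sheet plane, imaged as a
    Gaussian spot whose σ combines the bead's own extent (FWHM = diameter)
    with the lateral width of the detection PSF, and laterally offset by the
    ground-truth skew ``(k·z_step·sx, k·z_step·sy)``.  Rasterization uses
    ``supersample``× area sampling so sub-pixel centroids are stable.  The
    expected photons a fully-in-FOV bead contributes to slice k equal
    ``brightness × axial_weight(k)`` exactly.
    """
    n_cols, n_rows = (int(v) for v in geometry.fov_px)
    if n_cols <= 0 or n_rows <= 0:
        raise ValueError("empty FOV")
    rng = _rng(seed)
    pi = geometry.image_pixel_um
    sx, sy = geometry.skew_per_um
    if n_slices is None:
        n_slices = int(math.floor(phantom.volume_dims_um[2] / geometry.z_step_um)) + 1

    sigma_psf_um = 0.0
    if psf3d is not None:
        sigma_psf_um = psf3d.lateral_fwhm_px / (2.0 * math.sqrt(2.0 * math.log(2.0))) * pi

    sigma_bead_um = phantom.diameters_um / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    sigma_px = np.sqrt(sigma_bead_um**2 + sigma_psf_um**2) / pi

    frames = np.zeros((n_slices, exposure_frames, n_rows, n_cols))
    for k in range(n_slices):
        z_stage = k * geometry.z_step_um
        if phantom.n_beads:
            d = phantom.positions_um[:, 2] - z_stage
            weight = sheet.axial_weight(d)
            x_px = (phantom.positions_um[:, 0] + z_stage * sx) / pi
            y_px = (phantom.positions_um[:, 1] + z_stage * sy) / pi
            photons = phantom.brightness_photons * weight
            clean = _render_spots(
                (n_rows, n_cols), x_px, y_px, sigma_px, photons, supersample
            )
        else:
            clean = np.zeros((n_rows, n_cols))
        for f in range(exposure_frames):
            frames[k, f] = add_camera_noise(clean, noise, rng)
    meta = StackMeta(
        pixel_size_um=pi,
        z_step_um=geometry.z_step_um,
        skew=SkewEstimate(sx=sx, sy=sy, sheet_angle_phi_deg=geometry.sheet_angle_phi_deg),
    )
    return ImageStack(frames, meta)


# ---------------------------------------------------------------------------
# Diffusion movies
# ---------------------------------------------------------------------------

def simulate_diffusion_movie(
    spec: DiffusionSimSpec,
    geometry: AcquisitionGeometry,
    sheet: Optional[SheetProfile] = None,
    psf_sigma_um: float = 0.3,
    noise: NoiseModel = NoiseModel(kind="none", offset_counts=0.0),
    margin_um: Optional[float] = None,
    return_positions: bool = False,
):
    """Movie (time × rows × cols) of point emitters under 2D Brownian motion.

    Walkers take per-axis Gaussian steps of standard deviation
    √(2 D Δt) and reflect at the boundary of a walk region that extends
    ``margin_um`` beyond the FOV on every side (so pixels well inside the
    FOV see open diffusion).  If ``spec.region_mask`` is given (FOV-grid
    boolean map, True = accessible), steps landing in blocked pixels are
    rejected, emulating a porous matrix.  Each emitter is rendered as a 2D
    Gaussian of standard deviation ``psf_sigma_um`` integrating to
    ``brightness_photons`` per frame; if ``sheet`` is given, emitters carry
    a fixed random sheet-depth weight.
    """
    rng = _rng(spec.seed)
    n_cols, n_rows = (int(v) for v in geometry.fov_px)
    pi = geometry.image_pixel_um
    if margin_um is None:
        margin_um = 4.0 * psf_sigma_um
    lo = np.array([-margin_um, -margin_um])
    hi = np.array([n_cols * pi + margin_um, n_rows * pi + margin_um])
    extent = hi - lo

    pos = lo + rng.uniform(0.0, 1.0, size=(spec.n_walkers, 2)) * extent
    step_sd = math.sqrt(2.0 * spec.diffusion_um2_per_s * spec.frame_interval_s)

    weights = np.ones(spec.n_walkers)
    if sheet is not None:
        depth = rng.uniform(-sheet.thickness_um / 2.0, sheet.thickness_um / 2.0,
                            size=spec.n_walkers)
        weights = np.asarray(sheet.axial_weight(depth))

    mask = None
    if spec.region_mask is not None:
        mask = np.asarray(spec.region_mask, dtype=bool)
        if mask.shape != (n_rows, n_cols):
            raise ValueError("region_mask must match the FOV grid (rows, cols)")

    def blocked(p: np.ndarray) -> np.ndarray:
        if mask is None:
            return np.zeros(p.shape[0], dtype=bool)
        col = np.clip((p[:, 0] / pi).astype(int), 0, n_cols - 1)
        row = np.clip((p[:, 1] / pi).astype(int), 0, n_rows - 1)
        inside = (p[:, 0] >= 0) & (p[:, 0] < n_cols * pi) & \
                 (p[:, 1] >= 0) & (p[:, 1] < n_rows * pi)
        out = np.zeros(p.shape[0], dtype=bool)
        out[inside] = ~mask[row[inside], col[inside]]
        return out

    sigma_px = psf_sigma_um / pi
    yy = (np.arange(n_rows) + 0.5) * pi
    xx = (np.arange(n_cols) + 0.5) * pi

    movie = np.empty((spec.n_frames, n_rows, n_cols))
    positions = np.empty((spec.n_frames, spec.n_walkers, 2)) if return_positions else None
    for t in range(spec.n_frames):
        if t > 0 and step_sd > 0:
            trial = pos + rng.normal(0.0, step_sd, size=pos.shape)
            # reflect at the outer walk region
            for ax in range(2):
                over = trial[:, ax] > hi[ax]
                under = trial[:, ax] < lo[ax]
                trial[over, ax] = 2.0 * hi[ax] - trial[over, ax]
                trial[under, ax] = 2.0 * lo[ax] - trial[under, ax]
            trial = np.clip(trial, lo, hi)
            rej = blocked(trial)
            trial[rej] = pos[rej]
            pos = trial
        if positions is not None:
            positions[t] = pos
        dy = yy[:, None] - pos[None, :, 1]  # (rows, walkers)
        dx = xx[:, None] - pos[None, :, 0]  # (cols, walkers)
        gy = np.exp(-(dy**2) / (2.0 * psf_sigma_um**2))
        gx = np.exp(-(dx**2) / (2.0 * psf_sigma_um**2))
        amp = spec.brightness_photons * weights * pi**2 / (2.0 * math.pi * psf_sigma_um**2)
        clean = np.einsum("rw,cw,w->rc", gy, gx, amp)
        movie[t] = add_camera_noise(clean, noise, rng)
    if return_positions:
        return movie, positions
    return movie


# ---------------------------------------------------------------------------
# Camera noise
# ---------------------------------------------------------------------------

def add_camera_noise(photon_image: np.ndarray, noise: NoiseModel, seed=0) -> np.ndarray:
    """Convert an expected-photon image to noisy camera counts.

    Shot noise is Poisson; the EMCCD register is modelled as a Gamma
    distribution with shape = photoelectrons and scale = em_gain, whose
    variance (n·g²) reproduces the √2 excess noise factor; read noise is
    additive Gaussian; the offset is a constant baseline.
    """
    photons = np.asarray(photon_image, dtype=float)
    if np.any(photons < 0):
        raise ValueError("photon_image must be nonnegative")
    rng = _rng(seed)
    if noise.kind == "none":
        return photons + noise.offset_counts
    electrons = rng.poisson(photons).astype(float)
    if noise.kind == "emccd":
        amplified = np.zeros_like(electrons)
        nz = electrons > 0
        amplified[nz] = rng.gamma(shape=electrons[nz], scale=noise.em_gain)
        electrons = amplified
    if noise.read_noise_e > 0:
        electrons = electrons + rng.normal(0.0, noise.read_noise_e, size=electrons.shape)
    return electrons + noise.offset_counts


# ---------------------------------------------------------------------------
# Ground-truth physics
# ---------------------------------------------------------------------------

def stokes_einstein_D(
    hydrodynamic_radius_nm: float,
    temperature_K: float = 293.0,
    viscosity_mPa_s: float = 1.0,
) -> float:
    """Stokes–Einstein diffusion coefficient D = kB·T/(6π η r) in µm²/s.

    Defaults correspond to water at 293 K (η = 1.00 mPa·s), the conditions
    assumed when quoting the free diffusion of a ~9 nm-radius macromolecule.
    """
    if hydrodynamic_radius_nm <= 0 or temperature_K <= 0:
        raise ValueError("radius and temperature must be positive")
    if viscosity_mPa_s <= 0:
        raise ValueError("viscosity must be positive")
    r_m = hydrodynamic_radius_nm * 1e-9
    eta = viscosity_mPa_s * 1e-3  # Pa·s
    d_m2_s = BOLTZMANN_J_PER_K * temperature_K / (6.0 * math.pi * eta * r_m)
    return d_m2_s * 1e12  # m²/s -> µm²/s
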