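"""Closed-form optical design calculators for light-sheet microscopy.

This module collects the analytic relations a builder needs before touching
hardware: intensity profiles of the three beam families used to form sheets
(Gaussian, Bessel-from-axicon, exponentially apertured Airy), Gaussian-beam
propagation through a train of spherical and cylindrical lenses to predict
the sheet width and thickness, objective resolution and diffraction-limit
arithmetic, camera sampling (Nyquist) geometry, and the detection depth of
field.

Unit conventions
----------------
All lengths are micrometres internally.  Wavelengths are accepted in
micrometres inside beam specifications (where they sit next to waists of the
same magnitude) and in nanometres at the objective/camera API boundary,
where practitioners quote them in nm; every function name or argument states
its unit.  Angles are radians internally and in the beam specifications,
degrees at the calibration-facing API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import special

__all__ = [
    "GaussianBeamSpec",
    "AxiconSpec",
    "AirySpec",
    "LensElement",
    "ObjectiveSpec",
    "CameraSpec",
    "GaussianPropagation",
    "gaussian_intensity",
    "gaussian_intensity_peak_normalized",
    "gaussian_propagation",
    "waist_from_divergence",
    "axicon_parameter",
    "bessel_profile",
    "bessel_confocal",
    "airy_profile",
    "airy_propagation_bAi",
    "propagate_train",
    "TrainStage",
    "TrainResult",
    "objective_resolution",
    "lsm_psf",
    "image_pixel_size",
    "required_magnification",
    "expected_bead_psf_px",
    "depth_of_field",
]


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {value!r}")


def _check_finite(**kwargs) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianBeamSpec:
    """A TEM00 Gaussian beam.

    Parameters
    ----------
    wavelength_um:
        Vacuum wavelength in µm.
    waist_w0_um:
        1/e² intensity radius at the focus, µm.  The beam intensity falls to
        13.5 % of its on-axis value at this radius.
    refractive_index:
        Index of the propagation medium (≥ 1).
    beam_quality_m2:
        M² beam-quality factor (1 for a diffraction-limited beam).
    amplitude_i0:
        Intensity scale I0 in arbitrary units.
    """

    wavelength_um: float
    waist_w0_um: float
    refractive_index: float = 1.0
    beam_quality_m2: float = 1.0
    amplitude_i0: float = 1.0

    def __post_init__(self) -> None:
        _check_positive(
            wavelength_um=self.wavelength_um,
            waist_w0_um=self.waist_w0_um,
            amplitude_i0=self.amplitude_i0,
        )
        if self.refractive_index < 1.0:
            raise ValueError("refractive_index must be >= 1")
        if self.beam_quality_m2 < 1.0:
            raise ValueError("beam_quality_m2 must be >= 1")


@dataclass(frozen=True)
class AxiconSpec:
    """A refractive axicon characterised by its apex angle τ.

    The deflection (axicon parameter) α0 is derived from the base angle of
    the cone as α0 = (n − 1)(π − τ)/2; it may be overridden explicitly for
    non-refractive axicon realisations.
    """

    refractive_index: float
    apex_angle_tau_rad: float
    axicon_parameter_alpha0_rad: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.apex_angle_tau_rad < math.pi):
            raise ValueError("apex_angle_tau_rad must lie in (0, pi)")
        if self.refractive_index < 1.0:
            raise ValueError("refractive_index must be >= 1")
        if self.axicon_parameter_alpha0_rad is None:
            object.__setattr__(
                self,
                "axicon_parameter_alpha0_rad",
                axicon_parameter(self.refractive_index, self.apex_angle_tau_rad),
            )
        if not (0.0 < self.axicon_parameter_alpha0_rad < math.pi / 2):
            raise ValueError("axicon parameter alpha0 must lie in (0, pi/2)")


@dataclass(frozen=True)
class AirySpec:
    """An exponentially apertured Airy beam produced by a cubic phase mask."""

    characteristic_length_x0_um: float
    apodization_a: float
    phase_wraps_gamma: float
    wavelength_um: float

    def __post_init__(self) -> None:
        _check_positive(
            characteristic_length_x0_um=self.characteristic_length_x0_um,
            phase_wraps_gamma=self.phase_wraps_gamma,
            wavelength_um=self.wavelength_um,
        )
        if self.apodization_a < 0:
            raise ValueError("apodization_a must be >= 0")

    @property
    def wave_number_per_um(self) -> float:
        return 2.0 * math.pi / self.wavelength_um


@dataclass(frozen=True)
class LensElement:
    """One element of an illumination train.

    ``distance_from_upstream_focus_mm`` is the distance z of the lens from
    the focal point of the preceding element.  ``acting_axis`` distinguishes
    spherical lenses (``both``) from cylindrical ones that focus a single
    axis.
    """

    focal_length_mm: float
    distance_from_upstream_focus_mm: float = 0.0
    acting_axis: Literal["both", "x_only", "y_only"] = "both"

    def __post_init__(self) -> None:
        if self.focal_length_mm == 0:
            raise ValueError("focal_length_mm must be nonzero")
        if self.distance_from_upstream_focus_mm < 0:
            raise ValueError("distance_from_upstream_focus_mm must be >= 0")
        if self.acting_axis not in ("both", "x_only", "y_only"):
            raise ValueError("acting_axis must be 'both', 'x_only' or 'y_only'")


@dataclass(frozen=True)
class ObjectiveSpec:
    """A microscope objective plus the tube lens it is paired with."""

    magnification: float
    numerical_aperture: float
    immersion_index: float = 1.0
    tube_lens_focal_mm: float = 200.0
    working_distance_mm: float = 1.0

    def __post_init__(self) -> None:
        _check_positive(
            magnification=self.magnification,
            numerical_aperture=self.numerical_aperture,
            tube_lens_focal_mm=self.tube_lens_focal_mm,
        )
        if self.numerical_aperture > self.immersion_index:
            raise ValueError("numerical_aperture cannot exceed immersion_index")


@dataclass(frozen=True)
class CameraSpec:
    """Detector geometry and noise description used for sampling math."""

    physical_pixel_pp_um: float
    read_noise_e: float = 2.0
    offset_counts: float = 100.0
    gain_model: Literal["scmos", "emccd", "none"] = "scmos"
    em_gain: float = 1.0
    quantum_efficiency: float = 0.95

    def __post_init__(self) -> None:
        _check_positive(physical_pixel_pp_um=self.physical_pixel_pp_um)
        if not (0.0 < self.quantum_efficiency <= 1.0):
            raise ValueError("quantum_efficiency must be in (0, 1]")
        if self.read_noise_e < 0:
            raise ValueError("read_noise_e must be >= 0")


# ---------------------------------------------------------------------------
# Gaussian beams
# ---------------------------------------------------------------------------

def gaussian_intensity(beam: GaussianBeamSpec, r, z):
    """Intensity of a Gaussian beam at radial distance ``r`` and axial
    position ``z`` (both µm).

    Evaluates the profile exactly as
    ``I0 / (2π ω0² (1 + (z/zR)²)) · exp(−2r² / (ω0² (1 + (z/zR)²)))``
    with the Rayleigh range zR = π ω0² n / λ.  Note the prefactor makes I0
    an intensity *scale*, not the literal on-axis peak; use
    :func:`gaussian_intensity_peak_normalized` for a profile whose focal
    peak is exactly 1.
    """
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    _check_finite(r=r, z=z)
    w0 = beam.waist_w0_um
    zr = rayleigh_range(beam)
    spread = 1.0 + (z / zr) ** 2
    return beam.amplitude_i0 / (2.0 * math.pi * w0**2 * spread) * np.exp(
        -2.0 * r**2 / (w0**2 * spread)
    )


def gaussian_intensity_peak_normalized(beam: GaussianBeamSpec, r, z):
    """Gaussian profile normalized so that I(r=0, z=0) = 1."""
    peak = gaussian_intensity(beam, 0.0, 0.0)
    return gaussian_intensity(beam, r, z) / peak


def rayleigh_range(beam: GaussianBeamSpec) -> float:
    """Rayleigh range zR = π ω0² n / λ in µm."""
    return math.pi * beam.waist_w0_um**2 * beam.refractive_index / beam.wavelength_um


@dataclass(frozen=True)
class GaussianPropagation:
    """Propagation summary of a Gaussian beam."""

    rayleigh_range_zr_um: float
    confocal_parameter_b_um: float
    radius_at: Callable[[float], float] = field(repr=False)


def gaussian_propagation(beam: GaussianBeamSpec) -> GaussianPropagation:
    """Rayleigh range, confocal parameter b = 2 zR, and the beam-radius
    spreading function ω(z) = ω0 √(1 + (z/zR)²)."""
    zr = rayleigh_range(beam)

    def radius_at(z: float) -> float:
        return beam.waist_w0_um * math.sqrt(1.0 + (z / zr) ** 2)

    return GaussianPropagation(
        rayleigh_range_zr_um=zr,
        confocal_parameter_b_um=2.0 * zr,
        radius_at=radius_at,
    )


def waist_from_divergence(wavelength_um: float, divergence_theta_rad: float) -> float:
    """Beam waist ω0 = λ / (π θ) from the far-field divergence half-angle."""
    _check_positive(wavelength_um=wavelength_um)
    if divergence_theta_rad <= 0:
        raise ValueError("divergence_theta_rad must be positive (zero divergence "
                         "would imply an infinite waist)")
    return wavelength_um / (math.pi * divergence_theta_rad)


# ---------------------------------------------------------------------------
# Bessel beams from an axicon
# ---------------------------------------------------------------------------

def axicon_parameter(refractive_index: float, apex_angle_tau_rad: float) -> float:
    """Deflection angle α0 = (n − 1)(π − τ)/2 of an axicon of apex angle τ."""
    if not (0.0 < apex_angle_tau_rad < math.pi):
        raise ValueError("apex_angle_tau_rad must lie in (0, pi)")
    return (refractive_index - 1.0) * (math.pi - apex_angle_tau_rad) / 2.0


def bessel_confocal(input_waist_w0g_um: float, alpha0_rad: float) -> float:
    """Propagation range b_b = ω0g cos α0 / sin α0 of an axicon Bessel beam."""
    _check_positive(input_waist_w0g_um=input_waist_w0g_um)
    if alpha0_rad <= 0 or alpha0_rad >= math.pi / 2:
        raise ValueError("alpha0_rad must lie in (0, pi/2); alpha0 = 0 gives a "
                         "divergent propagation range")
    return input_waist_w0g_um * math.cos(alpha0_rad) / math.sin(alpha0_rad)


def bessel_profile(
    input_waist_w0g_um: float,
    axicon: AxiconSpec,
    wavelength_um: float,
    r,
    z,
    amplitude_i0: float = 1.0,
):
    """Intensity of a Bessel beam formed by passing a Gaussian beam of waist
    ω0g through an axicon:
    ``4 I0 k sin α0 ω0g (z / b_b) exp(−2 z²/b_b²) J0²(k r sin α0)``.
    """
    _check_positive(input_waist_w0g_um=input_waist_w0g_um, wavelength_um=wavelength_um)
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    _check_finite(r=r, z=z)
    alpha0 = axicon.axicon_parameter_alpha0_rad
    k = 2.0 * math.pi / wavelength_um
    bb = bessel_confocal(input_waist_w0g_um, alpha0)
    radial = special.j0(k * r * math.sin(alpha0)) ** 2
    axial = (z / bb) * np.exp(-2.0 * z**2 / bb**2)
    return 4.0 * amplitude_i0 * k * math.sin(alpha0) * input_waist_w0g_um * axial * radial


# ---------------------------------------------------------------------------
# Airy beams
# ---------------------------------------------------------------------------

def airy_profile(spec: AirySpec, x, y, z):
    """Intensity of an exponentially apertured Airy beam.

    The transverse argument of the Airy function acquires both a parabolic
    real shift and an imaginary part proportional to the apodization as the
    beam propagates, reproducing the characteristic accelerating main lobe.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    _check_finite(x=x, y=y, z=z)
    x0 = spec.characteristic_length_x0_um
    a = spec.apodization_a
    k = spec.wave_number_per_um
    zx = z / (k * x0**2)  # dimensionless propagation variable

    def one_axis(t):
        s = t / x0
        envelope = np.exp(2.0 * a * (s - zx**2 / 2.0))
        xi = s - zx**2 / 4.0 + 1j * a * zx
        (ai, _, _, _) = special.airy(xi)
        return envelope, ai

    env_x, ai_x = one_axis(x)
    env_y, ai_y = one_axis(y)
    return env_x * env_y * np.abs(ai_x * ai_y) ** 2


def airy_propagation_bAi(
    input_waist_w0g_um: float,
    phase_wraps_gamma: float,
    refractive_index: float = 1.0,
    wavelength_um: float = 0.532,
) -> float:
    """FWHM-based propagation length of an Airy sheet,
    b_Ai = ½ √(2 ln 2) · 2π n ω0g² / (γ λ).

    The grouping of the printed expression is typographically ambiguous in
    the source material; this function fixes one reading and is the single
    place to swap in a corrected form.
    """
    _check_positive(
        input_waist_w0g_um=input_waist_w0g_um,
        phase_wraps_gamma=phase_wraps_gamma,
        wavelength_um=wavelength_um,
    )
    return (
        0.5
        * math.sqrt(2.0 * math.log(2.0))
        * (2.0 * math.pi * refractive_index * input_waist_w0g_um**2)
        / (phase_wraps_gamma * wavelength_um)
    )


# ---------------------------------------------------------------------------
# Lens trains and sheet dimensions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainStage:
    """Beam state at one element of the train (diameters in µm)."""

    element: LensElement
    diameter_at_lens_x_um: float
    diameter_at_lens_y_um: float
    focused_diameter_x_um: float
    focused_diameter_y_um: float


@dataclass(frozen=True)
class TrainResult:
    stages: tuple
    sheet_width_um: float
    sheet_thickness_um: float


def propagate_train(
    beam: GaussianBeamSpec, train: Sequence[LensElement]
) -> TrainResult:
    """Propagate a Gaussian beam through an ordered train of spherical and
    cylindrical lenses and report the final sheet width × thickness.

    Each element refocuses the beam according to
    ``2ω' = 4 f λ M² / (π ω(z))`` where ω(z) is the beam radius arriving at
    the lens, a distance z from the upstream focus.  Cylindrical elements
    (``x_only``/``y_only``) act on their axis alone and leave the other axis
    untouched.  The final sheet width is the larger of the two orthogonal
    focused diameters and the thickness the smaller.
    """
    lam = beam.wavelength_um
    m2 = beam.beam_quality_m2
    n = beam.refractive_index
    waists = {"x": beam.waist_w0_um, "y": beam.waist_w0_um}
    stages = []
    for element in train:
        z_um = element.distance_from_upstream_focus_mm * 1e3
        f_um = abs(element.focal_length_mm) * 1e3
        at_lens = {}
        focused = {}
        for axis in ("x", "y"):
            w0 = waists[axis]
            zr = math.pi * w0**2 * n / lam
            at_lens[axis] = w0 * math.sqrt(1.0 + (z_um / zr) ** 2)
        for axis in ("x", "y"):
            acts = element.acting_axis == "both" or element.acting_axis == f"{axis}_only"
            if acts:
                if at_lens[axis] == 0:
                    raise ValueError("beam radius at lens is zero; cannot refocus")
                focused[axis] = 4.0 * f_um * lam * m2 / (math.pi * at_lens[axis])
                waists[axis] = focused[axis] / 2.0
            else:
                focused[axis] = 2.0 * waists[axis]
        stages.append(
            TrainStage(
                element=element,
                diameter_at_lens_x_um=2.0 * at_lens["x"],
                diameter_at_lens_y_um=2.0 * at_lens["y"],
                focused_diameter_x_um=focused["x"],
                focused_diameter_y_um=focused["y"],
            )
        )
    dx, dy = 2.0 * waists["x"], 2.0 * waists["y"]
    return TrainResult(
        stages=tuple(stages),
        sheet_width_um=max(dx, dy),
        sheet_thickness_um=min(dx, dy),
    )


# ---------------------------------------------------------------------------
# Objective math, sampling and depth of field
# ---------------------------------------------------------------------------

def objective_resolution(obj: ObjectiveSpec, emission_wavelength_nm: float) -> dict:
    """Objective focal length and diffraction-limited resolutions.

    Returns ``fobj_mm`` = ftl/M, lateral resolution ``lateral_rxy_nm`` =
    λ/(2 NA), axial resolution ``axial_rz_nm`` = 2λ/NA², and the Abbe
    diffraction limit ``diffraction_limit_d_nm`` = λ/(2 NA).
    """
    _check_positive(emission_wavelength_nm=emission_wavelength_nm)
    na = obj.numerical_aperture
    lam = emission_wavelength_nm
    return {
        "fobj_mm": obj.tube_lens_focal_mm / obj.magnification,
        "lateral_rxy_nm": lam / (2.0 * na),
        "axial_rz_nm": 2.0 * lam / na**2,
        "diffraction_limit_d_nm": lam / (2.0 * na),
    }


def lsm_psf(
    psf_illumination: np.ndarray,
    psf_detection: np.ndarray,
    normalize: bool | str = "auto",
) -> np.ndarray:
    """System PSF of a two-objective light-sheet microscope: the elementwise
    product of the illumination and detection PSFs.

    With ``normalize="auto"`` the product is rescaled to unit sum whenever
    both inputs are unit-sum (so kernels stay kernels); ``True``/``False``
    force the behaviour.
    """
    a = np.asarray(psf_illumination, dtype=float)
    b = np.asarray(psf_detection, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"PSF shapes differ: {a.shape} vs {b.shape}")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("PSFs must be nonnegative")
    out = a * b
    if normalize == "auto":
        normalize = abs(a.sum() - 1.0) < 1e-9 and abs(b.sum() - 1.0) < 1e-9
    if normalize:
        total = out.sum()
        if total == 0:
            raise ValueError("product PSF is identically zero; cannot normalize")
        out = out / total
    return out


def image_pixel_size(camera: CameraSpec | float, magnification: float) -> float:
    """Image-plane pixel size PI = PP / M in µm."""
    pp = camera.physical_pixel_pp_um if isinstance(camera, CameraSpec) else float(camera)
    _check_positive(physical_pixel_um=pp, magnification=magnification)
    return pp / magnification


def required_magnification(camera: CameraSpec | float, target_image_pixel_um: float) -> float:
    """Magnification M = PP / PI needed to reach a target image pixel size."""
    pp = camera.physical_pixel_pp_um if isinstance(camera, CameraSpec) else float(camera)
    _check_positive(physical_pixel_um=pp, target_image_pixel_um=target_image_pixel_um)
    return pp / target_image_pixel_um


def expected_bead_psf_px(bead_diameter_um: float, image_pixel_um: float) -> float:
    """Expected image extent of a bead, in pixels: diameter / PI."""
    _check_positive(bead_diameter_um=bead_diameter_um, image_pixel_um=image_pixel_um)
    return bead_diameter_um / image_pixel_um


def depth_of_field(
    emission_wavelength_nm: float,
    immersion_index: float,
    numerical_aperture: float,
    image_pixel_um: float,
    magnification: float,
) -> float:
    """Detection depth of field in µm:
    DOF = λn/NA² + n·PI/(M·NA), with λ the emission wavelength.

    The first term is the classical wave-optical DOF, the second the
    geometric contribution of finite pixel sampling.
    """
    _check_positive(
        emission_wavelength_nm=emission_wavelength_nm,
        immersion_index=immersion_index,
        numerical_aperture=numerical_aperture,
        magnification=magnification,
    )
    if image_pixel_um < 0:
        raise ValueError("image_pixel_um must be >= 0")
    lam_um = emission_wavelength_nm * 1e-3
    na = numerical_aperture
    n = immersion_index
    return lam_um * n / na**2 + n * image_pixel_um / (magnification * na)
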