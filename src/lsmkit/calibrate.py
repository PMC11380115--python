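"""Calibration procedures for a stage-scanned light-sheet instrument.

Four measurements turn a freshly aligned microscope into a quantitative
one: (i) sub-pixel localization of fluorescent beads of known size gives
the true image pixel size (bead diameter divided by fitted spot FWHM);
(ii) tracking beads while the stage steps in z gives the lateral skew
slopes (sx, sy) that the reconstruction must undo; (iii) the apparent
lateral shift per z-step yields the sheet angle via
φ = 90° − arctan(shift/Δz); (iv) second-moment principal-axis FWHMs of a
beam-profiler image give the sheet width and thickness at the sample
plane.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage, optimize

from .core import ImageStack, SkewEstimate

__all__ = [
    "BeadLocalization",
    "PixelSizeEstimate",
    "SheetDims",
    "localize_beads",
    "estimate_pixel_size",
    "measure_axial_skew",
    "sheet_angle_from_shift",
    "sheet_dims_from_profile",
]

logger = logging.getLogger(__name__)

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548


@dataclass
class BeadLocalization:
    """One fitted bead spot in one frame."""

    x_px: float
    y_px: float
    fwhm_px: float
    amplitude: float
    local_background: float
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.fwhm_px <= 0:
            raise ValueError("fwhm_px must be positive")


@dataclass
class PixelSizeEstimate:
    mean_um: float
    sd_um: float
    n: int

    def __post_init__(self) -> None:
        if self.mean_um <= 0:
            raise ValueError("mean_um must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class SheetDims:
    """Sheet FWHMs at the sample plane, µm; width >= thickness."""

    width_um: float
    thickness_um: float
    saturated: bool = False

    def __post_init__(self) -> None:
        if not (self.width_um >= self.thickness_um > 0):
            raise ValueError("require width_um >= thickness_um > 0")


# ---------------------------------------------------------------------------
# Localization
# ---------------------------------------------------------------------------

def _gauss2d(params, xx, yy):
    amp, x0, y0, sigma, bg = params
    return amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2)) + bg


def localize_beads(
    frame: np.ndarray,
    detection_threshold: float,
    window_px: int = 11,
    slice_index: int = 0,
) -> List[BeadLocalization]:
    """Detect and fit bead spots in a single frame.

    Local maxima above ``detection_threshold`` are refined by least-squares
    2D Gaussian fits (amplitude, center, σ, background) within an odd
    ``window_px`` box; fwhm = 2√(2 ln 2)·σ.  Fits that diverge, leave the
    window or land outside the frame are dropped (a debug log counts them).
    NaN pixels (e.g. deskew fill) are ignored during detection and fitting.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    if window_px % 2 == 0 or window_px < 5:
        raise ValueError("window_px must be odd and >= 5")
    half = window_px // 2

    work = np.where(np.isnan(frame), -np.inf, frame)
    footprint = np.ones((3, 3), dtype=bool)
    local_max = ndimage.maximum_filter(work, footprint=footprint, mode="nearest")
    peaks = (work == local_max) & (work > detection_threshold)
    peaks[:half, :] = peaks[-half:, :] = False
    peaks[:, :half] = peaks[:, -half:] = False
    rows, cols = np.nonzero(peaks)

    out: List[BeadLocalization] = []
    dropped = 0
    for r, c in zip(rows, cols):
        win = frame[r - half : r + half + 1, c - half : c + half + 1]
        valid = np.isfinite(win)
        if valid.sum() < 6:
            dropped += 1
            continue
        yy, xx = np.mgrid[r - half : r + half + 1, c - half : c + half + 1]
        f = win[valid]
        x = xx[valid].astype(float)
        y = yy[valid].astype(float)
        bg0 = float(np.nanmin(win))
        amp0 = float(frame[r, c] - bg0)
        p0 = [max(amp0, 1e-6), float(c), float(r), max(window_px / 6.0, 0.8), bg0]

        def resid(p):
            return _gauss2d(p, x, y) - f

        try:
            res = optimize.least_squares(resid, p0, method="lm", max_nfev=400)
        except Exception:
            dropped += 1
            continue
        amp, x0, y0, sigma, bg = res.x
        sigma = abs(sigma)
        in_window = abs(x0 - c) <= half and abs(y0 - r) <= half
        if not (res.success and in_window and sigma > 0.2 and amp > 0):
            dropped += 1
            continue
        out.append(
            BeadLocalization(
                x_px=float(x0),
                y_px=float(y0),
                fwhm_px=float(_FWHM_PER_SIGMA * sigma),
                amplitude=float(amp),
                local_background=float(bg),
                slice_index=slice_index,
            )
        )
    if dropped:
        logger.debug("localize_beads: dropped %d diverged/out-of-window fits", dropped)
    return out


# ---------------------------------------------------------------------------
# Pixel size
# ---------------------------------------------------------------------------

def estimate_pixel_size(
    bead_diameter_um: float, fwhms_px: Sequence[float]
) -> PixelSizeEstimate:
    """Pixel size from bead spots of known physical diameter.

    Each localization gives PI_i = diameter / fwhm_i; the estimate is the
    mean ± sd over localizations.
    """
    fwhms = np.asarray(list(fwhms_px), dtype=float)
    if fwhms.size == 0:
        raise ValueError("fwhms_px must be nonempty")
    if np.any(fwhms <= 0):
        raise ValueError("fwhms must be positive")
    if bead_diameter_um <= 0:
        raise ValueError("bead_diameter_um must be positive")
    per_loc = bead_diameter_um / fwhms
    sd = float(per_loc.std(ddof=1)) if per_loc.size > 1 else 0.0
    return PixelSizeEstimate(mean_um=float(per_loc.mean()), sd_um=sd, n=per_loc.size)


# ---------------------------------------------------------------------------
# Axial skew
# ---------------------------------------------------------------------------

def _link_tracks(per_slice, gate_px: float):
    """Greedy constant-velocity tracker.

    The first link uses a relaxed gate (5× ``gate_px``) because the skew
    itself can move a bead by more than the gate between slices; thereafter
    the gate applies to the residual from a constant-velocity prediction.
    """
    tracks = []  # list of lists of (slice_idx, x, y)
    lost = 0
    for k, locs in enumerate(per_slice):
        used = set()
        for tr in tracks:
            if tr[-1][0] != k - 1:
                continue
            if len(tr) >= 2:
                vx = tr[-1][1] - tr[-2][1]
                vy = tr[-1][2] - tr[-2][2]
                gate = gate_px
            else:
                vx = vy = 0.0
                gate = 5.0 * gate_px
            px, py = tr[-1][1] + vx, tr[-1][2] + vy
            best, best_d = None, gate
            for i, loc in enumerate(locs):
                if i in used:
                    continue
                d = math.hypot(loc.x_px - px, loc.y_px - py)
                if d < best_d:
                    best, best_d = i, d
            if best is None:
                lost += 1
            else:
                used.add(best)
                tr.append((k, locs[best].x_px, locs[best].y_px))
        for i, loc in enumerate(locs):
            if i not in used:
                tracks.append([(k, loc.x_px, loc.y_px)])
    return tracks, lost


def measure_axial_skew(
    stack: ImageStack,
    detection_threshold: float,
    window_px: int = 11,
    gate_px: float = 3.0,
    z_positions_um: Optional[Sequence[float]] = None,
    min_track_length: int = 3,
) -> SkewEstimate:
    """Skew slopes (sx, sy) from bead trajectories across a z-stack.

    Beads are localized per slice, linked across slices, and each track's
    centroid displacement (converted to µm with the pixel size) is fit
    against stage z by least squares.  The reported slopes are the
    track-length-weighted means; the sheet angle follows from sx via
    :func:`sheet_angle_from_shift`.  Untrackable beads are excluded and
    counted in the log.
    """
    if stack.n_slices < 3:
        raise ValueError("need >= 3 z positions to fit skew slopes")
    pi = stack.meta.pixel_size_um
    if z_positions_um is None:
        z_positions_um = np.arange(stack.n_slices) * stack.meta.z_step_um
    z_positions_um = np.asarray(z_positions_um, dtype=float)

    per_slice = [
        localize_beads(stack.data[k, 0], detection_threshold, window_px, slice_index=k)
        for k in range(stack.n_slices)
    ]
    tracks, lost = _link_tracks(per_slice, gate_px)
    if lost:
        logger.info("measure_axial_skew: %d beads lost between slices", lost)

    sx_list, sy_list, weights, residuals = [], [], [], []
    for tr in tracks:
        if len(tr) < min_track_length:
            continue
        ks = np.array([p[0] for p in tr])
        xs = np.array([p[1] for p in tr]) * pi
        ys = np.array([p[2] for p in tr]) * pi
        zs = z_positions_um[ks]
        px = np.polyfit(zs, xs - xs[0], 1)
        py = np.polyfit(zs, ys - ys[0], 1)
        sx_list.append(px[0])
        sy_list.append(py[0])
        weights.append(len(tr))
        residuals.append(
            np.sqrt(np.mean((np.polyval(px, zs) - (xs - xs[0])) ** 2
                            + (np.polyval(py, zs) - (ys - ys[0])) ** 2))
        )
    if not sx_list:
        raise ValueError("no bead could be tracked across >= "
                         f"{min_track_length} slices")
    w = np.asarray(weights, dtype=float)
    sx = float(np.average(sx_list, weights=w))
    sy = float(np.average(sy_list, weights=w))
    shift_mag = math.hypot(sx, sy) * stack.meta.z_step_um
    phi = sheet_angle_from_shift(shift_mag, stack.meta.z_step_um)
    return SkewEstimate(
        sx=sx,
        sy=sy,
        sheet_angle_phi_deg=phi,
        fit_residual_um=float(np.average(residuals, weights=w)),
        n_tracks=len(sx_list),
    )


def sheet_angle_from_shift(apparent_shift_um: float, z_step_um: float) -> float:
    """Sheet angle φ = 90° − arctan(shift/Δz) in degrees.

    A shift equal to the z-step corresponds to a 45° sheet; zero shift means
    the sheet is orthogonal to the scan axis (90°).
    """
    if z_step_um <= 0:
        raise ValueError("z_step_um must be positive")
    if apparent_shift_um < 0:
        raise ValueError("apparent_shift_um must be >= 0")
    return 90.0 - math.degrees(math.atan(apparent_shift_um / z_step_um))


# ---------------------------------------------------------------------------
# Sheet dimensions
# ---------------------------------------------------------------------------

def sheet_dims_from_profile(
    profile_image: np.ndarray,
    pixel_pitch_um: float,
    demagnification: float = 1.0,
    saturation_level: Optional[float] = None,
) -> SheetDims:
    """Sheet width and thickness from a beam-profiler image.

    The FWHMs are taken along the two principal axes of the intensity
    distribution (eigenvectors of the second-moment matrix, so the beam
    need not be aligned with the detector rows), converted to physical
    units with the profiler pixel pitch and divided by the objective
    demagnification to refer them to the sample plane.
    """
    img = np.asarray(profile_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("profile_image must be 2D")
    if pixel_pitch_um <= 0 or demagnification <= 0:
        raise ValueError("pixel_pitch_um and demagnification must be positive")
    saturated = False
    if saturation_level is not None:
        frac = np.mean(img >= saturation_level)
        if frac > 0.001:
            saturated = True
            logger.warning("sheet profile saturated: %.2f%% of pixels at level",
                           100.0 * frac)
    work = img - img.min()
    total = work.sum()
    if total <= 0:
        raise ValueError("profile image has no intensity")
    yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
    cx = (work * xx).sum() / total
    cy = (work * yy).sum() / total
    cov = np.empty((2, 2))
    cov[0, 0] = (work * (xx - cx) ** 2).sum() / total
    cov[1, 1] = (work * (yy - cy) ** 2).sum() / total
    cov[0, 1] = cov[1, 0] = (work * (xx - cx) * (yy - cy)).sum() / total
    eigvals = np.linalg.eigvalsh(cov)
    sigmas = np.sqrt(np.clip(eigvals, 0, None))
    scale = pixel_pitch_um / demagnification
    thickness, width = (_FWHM_PER_SIGMA * sigmas * scale)
    return SheetDims(width_um=float(width), thickness_um=float(thickness),
                     saturated=saturated)
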