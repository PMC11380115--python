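"""Static reconstruction pipeline for stage-scanned light-sheet stacks.

The pipeline runs in acquisition order: import/ROI → de-skew →
Richardson–Lucy 3D deconvolution → local mean+3σ background thresholding →
volume assembly, followed by line-section analysis of the result.  TIFF
stacks travel with a JSON metadata sidecar carrying the pixel size, z-step,
frame interval and skew calibration.

De-skewed slices acquire NaN-filled margins where the parallelogram
geometry vacated pixels; all statistics downstream (thresholding,
localization) ignore NaN.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import tifffile
from scipy import ndimage
from scipy.signal import fftconvolve

from .core import ImageStack, PSF3D, SkewEstimate, StackMeta, Volume

__all__ = [
    "read_stack",
    "write_stack",
    "deskew",
    "build_psf3d",
    "deconvolve_rl",
    "threshold_background",
    "threshold_stack",
    "assemble_volume",
    "line_section",
    "reconstruct_static",
]

logger = logging.getLogger(__name__)

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _meta_to_dict(meta: StackMeta) -> dict:
    d = {
        "PI_um": meta.pixel_size_um,
        "z_step_um": meta.z_step_um,
        "frame_interval_s": meta.frame_interval_s,
    }
    if meta.skew is not None:
        d["skew"] = {
            "sx": meta.skew.sx,
            "sy": meta.skew.sy,
            "phi_deg": meta.skew.sheet_angle_phi_deg,
        }
    return d


def _meta_from_dict(d: dict) -> StackMeta:
    skew = None
    if d.get("skew") is not None:
        s = d["skew"]
        skew = SkewEstimate(sx=s["sx"], sy=s.get("sy", 0.0),
                            sheet_angle_phi_deg=s.get("phi_deg", 90.0))
    return StackMeta(
        pixel_size_um=d["PI_um"],
        z_step_um=d["z_step_um"],
        frame_interval_s=d.get("frame_interval_s", 1.0),
        skew=skew,
    )


def write_stack(stack: ImageStack, path: Union[str, Path]) -> None:
    """Write a stack as a multi-page TIFF plus a JSON metadata sidecar.

    Pages are ordered slice-major, frame-minor; the array dtype is
    preserved (float data is stored as float32 TIFF).
    """
    path = Path(path)
    data = stack.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    s, f, r, c = data.shape
    tifffile.imwrite(path, data.reshape(s * f, r, c), photometric="minisblack")
    sidecar = _meta_to_dict(stack.meta)
    sidecar["n_slices"] = s
    sidecar["n_frames"] = f
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_stack(
    paths: Union[str, Path, Sequence[Union[str, Path]]],
    frame_range: Optional[Tuple[int, int]] = None,
    roi: Optional[Tuple[int, int, int, int]] = None,
    meta: Optional[StackMeta] = None,
) -> ImageStack:
    """Read one multi-page TIFF (with sidecar) or several single-slice files.

    Multiple paths are concatenated as z-slices in path-sorted order.  The
    user-facing ``roi`` is inclusive, ``(row_start, row_stop, col_start,
    col_stop)``, converted internally to half-open bounds; ``frame_range``
    is likewise inclusive.  Metadata comes from the first sidecar found
    unless ``meta`` is supplied.
    """
    if isinstance(paths, (str, Path)):
        path_list = [Path(paths)]
    else:
        path_list = sorted(Path(p) for p in paths)
    if not path_list:
        raise ValueError("no paths given")

    arrays = []
    for p in path_list:
        if not p.exists():
            raise FileNotFoundError(str(p))
        arr = tifffile.imread(p)
        if arr.ndim == 2:
            arr = arr[None]
        if meta is None and _sidecar_path(p).exists():
            side = json.loads(_sidecar_path(p).read_text())
            meta = _meta_from_dict(side)
            if len(path_list) == 1 and "n_slices" in side:
                s, f = side["n_slices"], side["n_frames"]
                arr = arr.reshape(s, f, *arr.shape[-2:])
        if arr.ndim == 3:  # pages of a single-slice movie / single-frame slices
            arr = arr[None] if len(path_list) > 1 else arr[:, None]
        arrays.append(arr)
    shapes = {a.shape[1:] for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"mismatched frame shapes across files: {shapes}")
    dtypes = {a.dtype for a in arrays}
    if len(dtypes) > 1:
        raise ValueError(f"mixed dtypes across files: {dtypes}")
    data = np.concatenate(arrays, axis=0)
    if meta is None:
        raise ValueError("no metadata sidecar found; pass meta= explicitly")
    if frame_range is not None:
        f0, f1 = frame_range
        if not (0 <= f0 <= f1 < data.shape[1]):
            raise ValueError("frame_range out of bounds")
        data = data[:, f0 : f1 + 1]
    if roi is not None:
        r0, r1, c0, c1 = roi
        if not (0 <= r0 <= r1 < data.shape[2] and 0 <= c0 <= c1 < data.shape[3]):
            raise ValueError("roi out of bounds")
        data = data[:, :, r0 : r1 + 1, c0 : c1 + 1]
    return ImageStack(data, meta)


# ---------------------------------------------------------------------------
# De-skew
# ---------------------------------------------------------------------------

def deskew(stack: ImageStack, skew: Optional[SkewEstimate] = None) -> ImageStack:
    """Undo the parallelogram geometry of stage-scanned acquisition.

    Slice k is translated by ``(−k·z_step·sx/PI, −k·z_step·sy/PI)`` pixels
    relative to slice 0, with bilinear interpolation for sub-pixel shifts.
    Vacated margins are NaN, which downstream statistics exclude.
    """
    if skew is None:
        skew = stack.meta.skew
    if skew is None:
        raise ValueError("no skew calibration available")
    pi = stack.meta.pixel_size_um
    dz = stack.meta.z_step_um
    out = np.empty(stack.data.shape, dtype=float)
    n_rows, n_cols = stack.data.shape[2:]
    for k in range(stack.n_slices):
        dx_px = k * dz * skew.sx / pi
        dy_px = k * dz * skew.sy / pi
        if abs(dx_px) >= n_cols or abs(dy_px) >= n_rows:
            raise ValueError(
                f"slice {k}: deskew shift ({dx_px:.1f}, {dy_px:.1f}) px exceeds frame"
            )
        for f in range(stack.n_frames):
            if dx_px == 0 and dy_px == 0:
                out[k, f] = stack.data[k, f]
            else:
                out[k, f] = ndimage.shift(
                    stack.data[k, f].astype(float),
                    shift=(-dy_px, -dx_px),
                    order=1,
                    mode="constant",
                    cval=np.nan,
                    prefilter=False,
                )
    meta = StackMeta(
        pixel_size_um=pi,
        z_step_um=dz,
        frame_interval_s=stack.meta.frame_interval_s,
        skew=None,  # corrected
    )
    return ImageStack(out, meta)


# ---------------------------------------------------------------------------
# PSF and deconvolution
# ---------------------------------------------------------------------------

def build_psf3d(
    lateral_fwhm_px: float,
    axial_fwhm_slices: float,
    kernel_dims: Tuple[int, int, int],
) -> PSF3D:
    """Separable 3D Gaussian kernel (z, y, x) with the requested FWHMs,
    normalized to unit sum.  ``kernel_dims`` must be odd."""
    if lateral_fwhm_px <= 0 or axial_fwhm_slices <= 0:
        raise ValueError("FWHMs must be positive")
    nz, ny, nx = kernel_dims
    if any(d % 2 == 0 or d < 1 for d in (nz, ny, nx)):
        raise ValueError("kernel_dims must be odd and positive")
    sig_lat = lateral_fwhm_px / _FWHM_PER_SIGMA
    sig_ax = axial_fwhm_slices / _FWHM_PER_SIGMA

    def axis_profile(n, sigma):
        u = np.arange(n) - n // 2
        return np.exp(-(u**2) / (2.0 * sigma**2))

    kz = axis_profile(nz, sig_ax)
    ky = axis_profile(ny, sig_lat)
    kx = axis_profile(nx, sig_lat)
    kernel = kz[:, None, None] * ky[None, :, None] * kx[None, None, :]
    kernel /= kernel.sum()
    return PSF3D(lateral_fwhm_px=lateral_fwhm_px,
                 axial_fwhm_slices=axial_fwhm_slices, kernel=kernel)


def deconvolve_rl(
    volume: np.ndarray,
    psf: PSF3D,
    n_iterations: int = 20,
    epsilon: float = 1e-4,
) -> np.ndarray:
    """Richardson–Lucy deconvolution of a 3D volume.

    Multiplicative maximum-likelihood updates with frequency-domain
    convolutions (fftconvolve), reflective padding at the boundary, and an
    early stop when the relative update norm falls below ``epsilon``.  The
    output is nonnegative by construction.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D")
    if np.any(vol < 0):
        raise ValueError("volume must be nonnegative")
    if not np.any(vol > 0):
        warnings.warn("all-zero volume passed to deconvolve_rl; returned unchanged")
        return vol.copy()
    kernel = psf.kernel
    pad = [(s // 2, s // 2) for s in kernel.shape]
    obs = np.pad(vol, pad, mode="reflect")
    est = np.full_like(obs, obs.mean())
    mirror = kernel[::-1, ::-1, ::-1]
    tiny = 1e-12
    for i in range(n_iterations):
        blurred = fftconvolve(est, kernel, mode="same")
        ratio = obs / np.maximum(blurred, tiny)
        update = fftconvolve(ratio, mirror, mode="same")
        new = np.clip(est * update, 0.0, None)
        delta = np.linalg.norm(new - est) / max(np.linalg.norm(est), tiny)
        est = new
        logger.debug("RL iteration %d: relative update %.3e", i + 1, delta)
        if delta < epsilon:
            break
    sl = tuple(slice(p0, est.shape[ax] - p1) for ax, (p0, p1) in enumerate(pad))
    return est[sl]


# ---------------------------------------------------------------------------
# Background thresholding
# ---------------------------------------------------------------------------

def threshold_background(frame: np.ndarray, tile_size: int = 16) -> np.ndarray:
    """Local mean+3σ background subtraction.

    The frame is tiled; each tile contributes mean + 3·sd of its (finite)
    pixels to a threshold map that is bilinearly interpolated between tile
    centers and subtracted, clipping at zero.  NaN pixels (deskew fill) are
    excluded from the statistics and map to zero in the output.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    if tile_size < 4:
        raise ValueError("tile_size must be >= 4")
    n_rows, n_cols = frame.shape
    if tile_size > min(n_rows, n_cols):
        raise ValueError("tile_size larger than frame")
    tr = n_rows // tile_size
    tc = n_cols // tile_size
    centers_r = (np.arange(tr) + 0.5) * (n_rows / tr)
    centers_c = (np.arange(tc) + 0.5) * (n_cols / tc)
    tile_map = np.zeros((tr, tc))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN tiles
        for i in range(tr):
            r0 = int(round(i * n_rows / tr))
            r1 = int(round((i + 1) * n_rows / tr))
            for j in range(tc):
                c0 = int(round(j * n_cols / tc))
                c1 = int(round((j + 1) * n_cols / tc))
                tile = frame[r0:r1, c0:c1]
                m = np.nanmean(tile)
                s = np.nanstd(tile)
                tile_map[i, j] = (m + 3.0 * s) if np.isfinite(m) else np.inf
    # bilinear interpolation between tile centers, clamped at the borders
    rows = np.clip(np.arange(n_rows) + 0.5, centers_r[0], centers_r[-1])
    cols = np.clip(np.arange(n_cols) + 0.5, centers_c[0], centers_c[-1])
    ri = np.interp(rows, centers_r, np.arange(tr))
    ci = np.interp(cols, centers_c, np.arange(tc))
    r0 = np.floor(ri).astype(int)
    c0 = np.floor(ci).astype(int)
    r1 = np.minimum(r0 + 1, tr - 1)
    c1 = np.minimum(c0 + 1, tc - 1)
    fr = (ri - r0)[:, None]
    fc = (ci - c0)[None, :]
    thr = (
        tile_map[np.ix_(r0, c0)] * (1 - fr) * (1 - fc)
        + tile_map[np.ix_(r1, c0)] * fr * (1 - fc)
        + tile_map[np.ix_(r0, c1)] * (1 - fr) * fc
        + tile_map[np.ix_(r1, c1)] * fr * fc
    )
    out = frame - thr
    out = np.where(np.isfinite(out), np.clip(out, 0.0, None), 0.0)
    return out


def threshold_stack(stack: ImageStack, tile_size: int = 16) -> ImageStack:
    """Apply :func:`threshold_background` to every frame of a stack."""
    out = np.empty(stack.data.shape, dtype=float)
    for k in range(stack.n_slices):
        for f in range(stack.n_frames):
            out[k, f] = threshold_background(stack.data[k, f], tile_size)
    return ImageStack(out, stack.meta)


# ---------------------------------------------------------------------------
# Volume assembly and analysis
# ---------------------------------------------------------------------------

def assemble_volume(stack: ImageStack) -> Volume:
    """Stack the per-slice images into a physically scaled voxel grid.

    Requires one frame per slice (static data, or dynamics already fused to
    one image per slice).  Voxel values are taken bit-exactly from the
    stack — assembly only attaches the physical scale (PI, PI, z_step).
    """
    if stack.n_frames != 1:
        raise ValueError("assemble_volume expects 1 frame per slice; fuse first")
    pi = stack.meta.pixel_size_um
    return Volume(
        voxels=stack.data[:, 0],
        physical_scale=(pi, pi, stack.meta.z_step_um),
    )


def line_section(
    image_or_volume,
    p0: Sequence[float],
    p1: Sequence[float],
    n_samples: int = 100,
    pixel_size_um: Optional[float] = None,
) -> dict:
    """Intensity profile along a segment, with the FWHM of its largest peak.

    ``p0``/``p1`` are (row, col) for 2D arrays or (z, row, col) for a
    :class:`Volume` (voxel coordinates).  Sampling is bilinear; the FWHM is
    measured around the profile maximum at half of (max − baseline) with the
    baseline taken as the profile minimum, linearly interpolating the
    half-crossings, and converted to µm via the physical scale.  When no
    half-crossing exists on both sides the FWHM is None and ``defined`` is
    False.
    """
    if isinstance(image_or_volume, Volume):
        data = image_or_volume.voxels
        scale = np.array(
            [image_or_volume.physical_scale[2],
             image_or_volume.physical_scale[1],
             image_or_volume.physical_scale[0]]
        )  # (z, y, x) per-axis µm/voxel
    else:
        data = np.asarray(image_or_volume, dtype=float)
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required for plain arrays")
        scale = np.full(data.ndim, float(pixel_size_um))
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if p0.shape != (data.ndim,) or p1.shape != (data.ndim,):
        raise ValueError("endpoints must match array dimensionality")
    if np.allclose(p0, p1):
        raise ValueError("zero-length segment")
    for p in (p0, p1):
        if np.any(p < 0) or np.any(p > np.array(data.shape) - 1):
            raise ValueError("endpoints out of bounds")
    t = np.linspace(0.0, 1.0, n_samples)
    coords = p0[:, None] * (1 - t) + p1[:, None] * t
    profile = ndimage.map_coordinates(data.astype(float), coords, order=1)
    length_um = float(np.linalg.norm((p1 - p0) * scale))
    step_um = length_um / (n_samples - 1)

    baseline = float(np.nanmin(profile))
    peak_idx = int(np.nanargmax(profile))
    half = baseline + (profile[peak_idx] - baseline) / 2.0

    def crossing(idx_range):
        prev = peak_idx
        for i in idx_range:
            if profile[i] <= half:
                denom = profile[prev] - profile[i]
                frac = (profile[prev] - half) / denom if denom > 0 else 1.0
                return prev + (i - prev) * frac
            prev = i
        return None

    left = crossing(range(peak_idx - 1, -1, -1))
    right = crossing(range(peak_idx + 1, n_samples))
    if left is None or right is None or profile[peak_idx] <= baseline:
        return {"profile": profile, "fwhm_um": None, "defined": False,
                "step_um": step_um}
    return {
        "profile": profile,
        "fwhm_um": float((right - left) * step_um),
        "defined": True,
        "step_um": step_um,
    }


# ---------------------------------------------------------------------------
# Full static chain
# ---------------------------------------------------------------------------

def reconstruct_static(
    stack: ImageStack,
    psf: PSF3D,
    skew: Optional[SkewEstimate] = None,
    n_iterations: int = 20,
    epsilon: float = 1e-4,
    tile_size: int = 16,
) -> Volume:
    """Run the full static pipeline: deskew → RL deconvolve → mean+3σ
    threshold → assemble.  Deskew is skipped when no calibration is
    attached and none is passed."""
    if skew is not None or stack.meta.skew is not None:
        stack = deskew(stack, skew)
    vol = stack.data[:, 0].astype(float)
    finite = np.isfinite(vol)
    filled = np.where(finite, vol, 0.0)
    decon = deconvolve_rl(filled, psf, n_iterations=n_iterations, epsilon=epsilon)
    decon = np.where(finite, decon, np.nan)
    stack2 = ImageStack(decon[:, None], stack.meta)
    stack2 = threshold_stack(stack2, tile_size=tile_size)
    return assemble_volume(stack2)
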