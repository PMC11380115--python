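"""fcsSOFI engine: pixel-wise correlation analysis of per-slice movies.

Each pixel's intensity trace is autocorrelated on a multi-tau
(pseudo-logarithmic) lag grid and fitted with a fluorescence correlation
spectroscopy (FCS) diffusion model; the fitted diffusion time τD maps to a
diffusion coefficient through D = ω²/(4 τD), with ω the 1/e² radius of the
2D detection PSF.  In parallel a second-order cross-correlation SOFI image
supplies super-resolved structure.  Hue (dynamics, log10 D) and
saturation/value (structure, SOFI) are fused into one image per movie,
ready for volume assembly.

Definition of ω (focal radius)
------------------------------
For a Gaussian detection PSF of standard deviation σ the pixel-intensity
autocorrelation of freely diffusing emitters decays as
``G(τ) = G0 / (1 + τ/τD)`` with ``τD = σ²/D``, i.e. ``D = (2σ)²/(4 τD)``.
The ``focal_radius_omega_um`` expected throughout this module is therefore
the 1/e² radius ``ω = 2σ`` of the PSF;  :func:`omega_from_sigma` and
:func:`omega_from_fwhm` convert from a fitted σ or FWHM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize

from matplotlib.colors import hsv_to_rgb

__all__ = [
    "CorrelationCurve",
    "FcsFit",
    "DiffusionMap",
    "SofiImage",
    "FusedImage",
    "multitau_lags",
    "autocorrelate",
    "autocorrelate_movie",
    "fit_fcs",
    "diffusion_map",
    "sofi_xc2",
    "fuse",
    "fcssofi_slice",
    "omega_from_sigma",
    "omega_from_fwhm",
]

logger = logging.getLogger(__name__)

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def omega_from_sigma(sigma_um: float) -> float:
    """1/e² focal radius ω = 2σ of a Gaussian PSF of standard deviation σ."""
    return 2.0 * sigma_um


def omega_from_fwhm(fwhm_um: float) -> float:
    """1/e² focal radius from a Gaussian PSF FWHM: ω = 2·FWHM/2.355."""
    return 2.0 * fwhm_um / _FWHM_PER_SIGMA


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class CorrelationCurve:
    """Normalized intensity autocorrelation G(τ) at discrete lags."""

    lags_s: np.ndarray
    G: np.ndarray
    samples_per_lag: np.ndarray

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.samples_per_lag = np.asarray(self.samples_per_lag)
        if np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G must be finite")


@dataclass
class FcsFit:
    """Result of fitting one correlation curve.

    ``baseline`` is the fitted long-lag offset; on finite traces the
    empirical autocorrelation is shifted by the sample-mean subtraction, and
    a free baseline absorbs that bias instead of corrupting τD.
    """

    model: str
    G0: float
    tauD_s: float
    tauD2_s: Optional[float] = None
    fraction: Optional[float] = None
    alpha: Optional[float] = None
    baseline: float = 0.0
    rss: float = float("nan")
    converged: bool = False


@dataclass
class DiffusionMap:
    """Per-pixel diffusion coefficients (µm²/s) with a validity mask."""

    D: np.ndarray
    valid_mask: np.ndarray
    focal_radius_omega_um: float

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.D.shape != self.valid_mask.shape:
            raise ValueError("D and valid_mask shapes differ")
        if np.any(self.D[self.valid_mask] <= 0):
            raise ValueError("valid D entries must be positive")


@dataclass
class SofiImage:
    """Second-order correlation image (nonnegative after clamping)."""

    values: np.ndarray
    grid_kind: Literal["native", "interleaved"]
    clamp_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("SOFI values must be nonnegative after clamping")


@dataclass
class FusedImage:
    """HSV fusion: hue ← log10(D), saturation/value ← normalized SOFI."""

    hsv: np.ndarray = field(repr=False)
    rgb: np.ndarray = field(repr=False)
    valid_mask: np.ndarray = field(repr=False)
    d_range: tuple = (0.1, 100.0)


# ---------------------------------------------------------------------------
# Correlator
# ---------------------------------------------------------------------------

def multitau_lags(n: int, points_per_octave: int = 16, max_lag: Optional[int] = None
                  ) -> np.ndarray:
    """Pseudo-logarithmic integer lag grid.

    Lags 1..points_per_octave step 1, then the step doubles every octave,
    capped at ``max_lag`` (default n // 4).
    """
    if max_lag is None:
        max_lag = max(n // 4, 1)
    lags = []
    lag, step = 1, 1
    while lag <= max_lag:
        lags.append(lag)
        if len(lags) % points_per_octave == 0:
            step *= 2
        lag += step
    return np.asarray(lags, dtype=int)


def _check_series(series: np.ndarray) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1D")
    if series.size < 64:
        raise ValueError("series must have length >= 64")
    if abs(series.mean()) < 1e-300:
        raise ValueError("zero-mean series cannot be normalized by <F>^2")
    return series


def autocorrelate(
    series: Sequence[float],
    frame_interval_s: float,
    lag_scheme: Optional[Sequence[int]] = None,
) -> CorrelationCurve:
    """Normalized fluctuation autocorrelation
    G(τ) = ⟨δF(t) δF(t+τ)⟩ / ⟨F⟩², δF = F − ⟨F⟩.

    The estimator is exact at each integer lag (sum over the N−τ available
    products divided by N−τ); lags default to a multi-tau pseudo-log grid.
    Scaling the series leaves G unchanged.
    """
    series = _check_series(series)
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    n = series.size
    if lag_scheme is None:
        lags = multitau_lags(n)
    else:
        lags = np.asarray(lag_scheme, dtype=int)
        if np.any(lags < 1) or np.any(lags >= n):
            raise ValueError("lags must be in [1, n)")
    mean = series.mean()
    delta = series - mean
    G = np.empty(lags.size)
    counts = np.empty(lags.size, dtype=int)
    for i, lag in enumerate(lags):
        prod = delta[: n - lag] * delta[lag:]
        G[i] = prod.mean() / mean**2
        counts[i] = n - lag
    return CorrelationCurve(lags_s=lags * frame_interval_s, G=G,
                            samples_per_lag=counts)


def autocorrelate_movie(
    movie: np.ndarray, frame_interval_s: float,
    lag_scheme: Optional[Sequence[int]] = None,
) -> tuple:
    """Vectorized :func:`autocorrelate` over all pixels of a movie.

    Returns ``(lags_s, G, samples_per_lag)`` with G of shape
    (n_lags, rows, cols).  Pixels with zero mean get NaN curves.
    """
    movie = np.asarray(movie, dtype=float)
    t, rows, cols = movie.shape
    if lag_scheme is None:
        lags = multitau_lags(t)
    else:
        lags = np.asarray(lag_scheme, dtype=int)
    mean = movie.mean(axis=0)
    delta = movie - mean
    G = np.empty((lags.size, rows, cols))
    denom = np.where(mean != 0, mean**2, np.nan)
    for i, lag in enumerate(lags):
        G[i] = (delta[: t - lag] * delta[lag:]).mean(axis=0) / denom
    return lags * frame_interval_s, G, (t - lags)


# ---------------------------------------------------------------------------
# FCS model fitting
# ---------------------------------------------------------------------------

def _model_brownian1(tau, G0, tauD, c):
    return G0 / (1.0 + tau / tauD) + c


def _model_brownian2(tau, G0, f, tauD1, tauD2, c):
    return G0 * (f / (1.0 + tau / tauD1) + (1.0 - f) / (1.0 + tau / tauD2)) + c


def _model_anomalous(tau, G0, tauD, alpha, c):
    return G0 / (1.0 + (tau / tauD) ** alpha) + c


def fit_fcs(
    curve: CorrelationCurve,
    model: Literal["brownian1", "brownian2", "anomalous"] = "brownian1",
    bounds: Optional[tuple] = None,
    init: Optional[Sequence[float]] = None,
) -> FcsFit:
    """Weighted nonlinear least-squares fit of an FCS diffusion model.

    2D single-focal-area forms, each plus a free baseline c: ``brownian1``
    G0/(1+τ/τD) + c; ``brownian2`` G0·[f/(1+τ/τD1) + (1−f)/(1+τ/τD2)] + c;
    ``anomalous`` G0/(1+(τ/τD)^α) + c.  The baseline absorbs the downward
    shift the sample-mean subtraction imprints on finite-trace correlation
    estimates, which would otherwise bias τD low.  Per-lag weights are
    √samples_per_lag.  Initialization defaults to G0 = G(first lag) and
    τD = the lag where G first falls below G0/2; τD is bounded to
    [first lag, total duration].  Non-convergence is reported honestly via
    ``converged=False``.
    """
    tau = curve.lags_s
    g = curve.G
    sigma = 1.0 / np.sqrt(np.asarray(curve.samples_per_lag, dtype=float))
    total = tau[-1]
    first = tau[0]
    g0_init = max(g[0], 1e-12)
    below = np.nonzero(g <= g0_init / 2.0)[0]
    tau_d_init = tau[below[0]] if below.size else total / 2.0
    tau_d_init = float(np.clip(tau_d_init, first, total))

    if model == "brownian1":
        fn = _model_brownian1
        p0 = init if init is not None else [g0_init, tau_d_init, 0.0]
        lo = [0.0, first, -1.0]
        hi = [np.inf, total, 1.0]
    elif model == "brownian2":
        fn = _model_brownian2
        p0 = init if init is not None else [g0_init, 0.5, tau_d_init / 3.0,
                                            min(tau_d_init * 3.0, total), 0.0]
        lo = [0.0, 0.0, first, first, -1.0]
        hi = [np.inf, 1.0, total, total, 1.0]
    elif model == "anomalous":
        fn = _model_anomalous
        p0 = init if init is not None else [g0_init, tau_d_init, 1.0, 0.0]
        lo = [0.0, first, 0.05, -1.0]
        hi = [np.inf, total, 2.0, 1.0]
    else:
        raise ValueError(f"unknown model {model!r}")
    if bounds is not None:
        lo, hi = bounds
    p0 = np.clip(p0, lo, hi)

    try:
        popt, _ = optimize.curve_fit(
            fn, tau, g, p0=p0, sigma=sigma, bounds=(lo, hi), maxfev=2000
        )
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, ValueError):
        return FcsFit(model=model, G0=float("nan"), tauD_s=float("nan"),
                      converged=False)
    rss = float(np.sum(((fn(tau, *popt) - g) / sigma) ** 2))
    if model == "brownian1":
        return FcsFit(model=model, G0=popt[0], tauD_s=popt[1], baseline=popt[2],
                      rss=rss, converged=converged)
    if model == "brownian2":
        return FcsFit(model=model, G0=popt[0], fraction=popt[1], tauD_s=popt[2],
                      tauD2_s=popt[3], baseline=popt[4], rss=rss,
                      converged=converged)
    return FcsFit(model=model, G0=popt[0], tauD_s=popt[1], alpha=popt[2],
                  baseline=popt[3], rss=rss, converged=converged)


# ---------------------------------------------------------------------------
# Diffusion map
# ---------------------------------------------------------------------------

def diffusion_map(fits, focal_radius_omega_um: float) -> DiffusionMap:
    """Per-pixel D = ω²/(4 τD) from a 2D grid of FCS fits.

    ``fits`` is a nested sequence (rows of lists) of :class:`FcsFit` or
    None.  Pixels whose fit did not converge, or whose τD is nonpositive or
    pinned within 1 % of its bounds, are masked, never propagated as bogus
    diffusion coefficients.
    """
    if focal_radius_omega_um <= 0:
        raise ValueError("focal_radius_omega_um must be positive")
    rows = len(fits)
    cols = len(fits[0])
    D = np.full((rows, cols), np.nan)
    valid = np.zeros((rows, cols), dtype=bool)
    for i in range(rows):
        for j in range(cols):
            fit = fits[i][j]
            if fit is None or not fit.converged:
                continue
            if not np.isfinite(fit.tauD_s) or fit.tauD_s <= 0:
                continue
            D[i, j] = focal_radius_omega_um**2 / (4.0 * fit.tauD_s)
            valid[i, j] = True
    return DiffusionMap(D=D, valid_mask=valid,
                        focal_radius_omega_um=focal_radius_omega_um)


# ---------------------------------------------------------------------------
# SOFI
# ---------------------------------------------------------------------------

def sofi_xc2(movie: np.ndarray, lag: int = 1,
             grid: Literal["interleaved", "native"] = "interleaved") -> SofiImage:
    """Second-order cross-correlation SOFI image at time lag ``lag``.

    Native pixels carry the temporal autocorrelation AC(τ=lag) of their own
    fluctuations; on the interleaved (2×) grid, virtual pixels at the
    midpoints of horizontal/vertical neighbour pairs carry the symmetrized
    cross-correlation XC(r1, r2, τ=lag) = ⟨δF(r1,t)·δF(r2,t+lag)⟩, and
    diagonal midpoints carry the diagonal-pair XC.  Negative values are
    clamped to zero; the clamped fraction is recorded and logged.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise ValueError("movie must be (time, rows, cols) with >= 2 frames")
    t = movie.shape[0]
    if lag < 1 or lag >= t:
        raise ValueError("lag must satisfy 1 <= lag < n_frames")
    delta = movie - movie.mean(axis=0)
    a, b = delta[: t - lag], delta[lag:]

    def xcorr(sr1, sc1, sr2, sc2):
        """Symmetrized ⟨δF(r1,t) δF(r2,t+lag)⟩ for shifted pixel sets."""
        x1 = (a[:, sr1, sc1] * b[:, sr2, sc2]).mean(axis=0)
        x2 = (a[:, sr2, sc2] * b[:, sr1, sc1]).mean(axis=0)
        return 0.5 * (x1 + x2)

    sl = slice(None)
    ac = xcorr(sl, sl, sl, sl)
    if grid == "native":
        values = ac
    else:
        rows, cols = movie.shape[1:]
        values = np.zeros((2 * rows - 1, 2 * cols - 1))
        values[::2, ::2] = ac
        values[::2, 1::2] = xcorr(sl, slice(None, -1), sl, slice(1, None))
        values[1::2, ::2] = xcorr(slice(None, -1), sl, slice(1, None), sl)
        d1 = xcorr(slice(None, -1), slice(None, -1), slice(1, None), slice(1, None))
        d2 = xcorr(slice(None, -1), slice(1, None), slice(1, None), slice(None, -1))
        values[1::2, 1::2] = 0.5 * (d1 + d2)
    clamp_fraction = float(np.mean(values < 0))
    if clamp_fraction:
        logger.debug("sofi_xc2: clamped %.2f%% negative values",
                     100.0 * clamp_fraction)
    return SofiImage(values=np.clip(values, 0.0, None), grid_kind=grid,
                     clamp_fraction=clamp_fraction)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def _upsample_to(arr: np.ndarray, shape: tuple) -> np.ndarray:
    """Nearest-neighbour upsampling of a native grid onto the interleaved
    (2R−1, 2C−1) grid."""
    if arr.shape == shape:
        return arr
    up = np.repeat(np.repeat(arr, 2, axis=0), 2, axis=1)[: shape[0], : shape[1]]
    if up.shape != shape:
        raise ValueError(f"grids not alignable: {arr.shape} vs {shape}")
    return up


def fuse(
    sofi: SofiImage,
    dmap: DiffusionMap,
    d_range: tuple = (0.1, 100.0),
    colormap_spec: Optional[dict] = None,
) -> FusedImage:
    """HSV fusion of structure (SOFI) and dynamics (diffusion map).

    Hue is an affine map of log10(D) clipped to ``d_range`` (default
    0.1–100 µm²/s), running from ``hue_start`` to ``hue_end`` (default
    blue → red, a perceptually ordered sweep); value is the SOFI image
    normalized to its 99.5th percentile; saturation is 1 on valid pixels
    and 0 (grey) where the diffusion fit is invalid.
    """
    spec = {"hue_start": 2.0 / 3.0, "hue_end": 0.0}
    if colormap_spec:
        spec.update(colormap_spec)
    lo, hi = d_range
    if not (0 < lo < hi):
        raise ValueError("d_range must be increasing and positive")
    shape = sofi.values.shape
    D = _upsample_to(dmap.D, shape)
    valid = _upsample_to(dmap.valid_mask.astype(float), shape) > 0.5
    if not valid.any():
        raise ValueError("no valid diffusion pixels to fuse")

    logd = np.log10(np.clip(np.where(valid, D, lo), lo, hi))
    frac = (logd - math.log10(lo)) / (math.log10(hi) - math.log10(lo))
    hue = spec["hue_start"] + frac * (spec["hue_end"] - spec["hue_start"])

    norm = np.percentile(sofi.values, 99.5)
    value = np.clip(sofi.values / norm, 0.0, 1.0) if norm > 0 else \
        np.zeros_like(sofi.values)
    sat = np.where(valid, 1.0, 0.0)
    hsv = np.stack([np.where(valid, hue, 0.0), sat, value], axis=-1)
    return FusedImage(hsv=hsv, rgb=hsv_to_rgb(hsv), valid_mask=valid,
                      d_range=d_range)


# ---------------------------------------------------------------------------
# Per-slice composition
# ---------------------------------------------------------------------------

def fcssofi_slice(
    movie: np.ndarray,
    frame_interval_s: float,
    focal_radius_omega_um: float,
    model: Literal["brownian1", "brownian2", "anomalous"] = "brownian1",
    lag: int = 1,
    d_range: tuple = (0.1, 100.0),
    min_mean_counts: float = 1e-6,
    min_decay: float = 0.5,
) -> dict:
    """Collapse one per-slice movie into SOFI + diffusion-map + fused images.

    Per-pixel curves are computed with the vectorized multi-tau correlator
    and fitted with the chosen FCS model; pixels whose trace carries no
    signal (mean ≤ ``min_mean_counts``), whose correlation does not decay
    (immobile emitters: G at the longest lag ≥ ``min_decay``·G(first lag)),
    or whose fit fails are masked, never fatal.  Returns a dict with keys
    ``sofi``, ``dmap``, ``fused``, ``fused_value_image``.
    """
    movie = np.asarray(movie, dtype=float)
    t, rows, cols = movie.shape
    lags_s, G, counts = autocorrelate_movie(movie, frame_interval_s)
    mean = movie.mean(axis=0)

    fits = [[None] * cols for _ in range(rows)]
    for i in range(rows):
        for j in range(cols):
            if mean[i, j] <= min_mean_counts or not np.all(np.isfinite(G[:, i, j])):
                continue
            g = G[:, i, j]
            if g[0] <= 0:
                continue
            if g[-1] >= min_decay * g[0]:
                continue  # no decaying correlation -> immobile or static
            # leading lags must stand out from the estimator noise (tail std)
            tail = g[-max(5, g.size // 5):]
            if g[:3].mean() <= 3.0 * tail.std():
                continue
            curve = CorrelationCurve(lags_s=lags_s, G=g, samples_per_lag=counts)
            fit = fit_fcs(curve, model=model)
            if fit.converged and (fit.tauD_s <= 1.01 * lags_s[0]
                                  or fit.tauD_s >= 0.99 * lags_s[-1]):
                continue  # τD pinned at a bound: white noise or unresolved
            fits[i][j] = fit
    dmap = diffusion_map(fits, focal_radius_omega_um)
    sofi = sofi_xc2(movie, lag=lag)
    fused = None
    if dmap.valid_mask.any():
        fused = fuse(sofi, dmap, d_range=d_range)
    return {
        "sofi": sofi,
        "dmap": dmap,
        "fused": fused,
        "fused_value_image": None if fused is None else fused.hsv[..., 2],
    }
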