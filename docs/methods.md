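# Methods

This note records the models implemented in lsmkit, the assumptions behind
them, the defaults that matter, and what the synthetic-data generator does
and does not emulate.

## Optical calculators (`lsmkit.optics`)

All lengths are micrometres internally; wavelengths cross the API in nm on
the detection side (objectives, cameras, DOF) because that is how they are
quoted in practice, and in µm inside beam specifications.  Angles are
radians internally, degrees at the calibration-facing API.

* **Gaussian beams.** The intensity profile is implemented with the
  prefactor I₀/(2π ω₀²(1+(z/z_R)²)); under this normalization I₀ is an
  intensity *scale* rather than the literal on-axis peak, so a
  peak-normalized accessor is provided.  All tests and downstream uses rely
  on intensity ratios, which are prefactor-independent.  The far-field
  relation ω₀ = λ/(πθ) is used without higher-order corrections.
* **Axicon (Bessel) beams.** The deflection angle is taken as
  α₀ = (n−1)(π−τ)/2 — the refraction of a ray through the base angle of an
  axicon with apex angle τ.  The propagation range is b_b = ω₀ cos α₀/sin α₀;
  α₀ = 0 is rejected as divergent.
* **Airy beams.** The propagation length is computed as
  b_Ai = ½√(2 ln 2)·2πnω₀²/(γλ) with γ the number of phase wraps at the
  waist.  The grouping of this expression is fixed in one function
  (`airy_propagation_bAi`) so an alternative reading can be swapped in
  without touching callers.
* **Lens trains.** Each element applies 2ω′ = 4fλM²/(πω(z)) with ω(z) the
  beam radius arriving at the lens (z measured from the upstream focus).
  Cylindrical elements act on one axis and leave the other bitwise
  untouched.  The final sheet width/thickness are the larger/smaller of the
  two orthogonal focused diameters.
* **Resolution labels.** Lateral resolution is λ/(2NA) and axial is
  2λ/NA².  (Prose sources occasionally swap the two labels for the same
  numbers; the formulas are authoritative here.)
* **Sampling.** The ideal image pixel is PI = PP/M = 6.5/40 = 0.1625 µm for
  the reference camera/objective pair; expected bead image sizes in pixels
  are diameter/PI computed from this unrounded value.

## Synthetic data (`lsmkit.simulate`)

The generator is first-class code: every downstream stage is tested
against its ground truth.

**Bead phantoms.** Positions are uniform in the volume; diameters are
truncated-normal (> 0).  A bead of diameter b is rendered as a Gaussian
blob with FWHM = b — the one-parameter stand-in for a filled sphere's
projection that matches how bead images are treated as PSF-broadened spots
during calibration.  The rendered spot σ combines bead and detection-PSF
widths in quadrature.  Rasterization evaluates the spot on a 4×
supersampled grid and bins by area, keeping sub-pixel centroids stable to
≲0.01 px.  At stage position k·Δz a bead at depth z is excited with weight
exp(−2d²/ω²), d = z − k·Δz, ω = thickness/2 (thickness = full 1/e² width,
consistent with the Gaussian-waist convention), and shifted laterally by
k·Δz·(sx, sy) — the ground-truth skew.  A fully-in-view bead therefore
contributes exactly brightness × weight photons per slice, which the
photon-conservation tests exploit.

**Camera noise.** sCMOS: Poisson shot noise + Gaussian read noise +
offset.  EMCCD: the EM register is modelled as a Gamma distribution with
shape = photoelectrons and scale = gain, giving mean n·g and variance
n·g² — the √2 excess-noise factor.  Pixel-dependent (fixed-pattern) sCMOS
noise is *not* modelled.

**Diffusion movies.** Walkers take per-axis Gaussian steps of standard
deviation √(2DΔt) and reflect at the boundary of a walk region that
extends a configurable margin beyond the field of view; a binary region
mask (porous matrix) is honoured by rejecting steps into blocked pixels.
Emitters are rendered as 2D Gaussians of standard deviation σ_PSF
integrating to `brightness` photons per frame.  Two idealisations matter
for interpretation: positions are sampled once per frame (no intra-frame
motion blur), and blinking/photobleaching are absent.  Passing tests on
these movies therefore demonstrate the correctness of the correlation →
fit → Eq.-of-diffusion chain, not robustness to photophysics.

*Study conditions used by the recovery tests and the acceptance script*
(chosen once, as a realistic emulation of fluorescent dextran diffusing in
an agarose gel imaged at 2 ms frames): PI = 0.1625 µm, 24×24 px field,
σ_PSF = 0.3 µm (FWHM 0.71 µm), walk region extending 6 µm beyond the FOV,
300 walkers (≈0.95 µm⁻²), 300 photons/frame/emitter, sCMOS noise
(2 e⁻ read, offset 100), 5000 frames; the recovery criterion pools the
per-pixel medians of four independent movies per diffusion level.  The
margin is deliberately large: a walk region comparable to the field of
view is a closed box whose conserved walker number anticorrelates the
correlation tail and biases τ_D low by tens of percent, which is not how a
macroscopic sample behaves.

**Stokes–Einstein.** D = k_B·T/(6πηr), with 293 K water (η = 1.00 mPa·s)
as the default conditions; sources quoting "≈24 µm²/s" for a 9 nm-radius
macromolecule do not state T and η, so these defaults are documented here.

## Calibration (`lsmkit.calibrate`)

* **Localization** is threshold → 3×3 local maxima → windowed least-squares
  2D Gaussian fit (amplitude, centre, σ, background); FWHM = 2√(2 ln 2)·σ.
  Diverged fits and fits leaving the window are dropped and counted.
* **Pixel size** is the mean ± sd over localizations of
  diameter/FWHM.  With 2 µm beads and a ≈0.47 µm-FWHM PSF the quadrature
  broadening biases the estimate low by ≈3 %, inside the 5 % acceptance
  band; smaller beads would need a deconvolution of the PSF contribution.
* **Skew** links per-slice localizations into tracks and least-squares fits
  centroid displacement (µm) against stage z.  Linking is
  constant-velocity-predictive with a 3 px gate on the prediction residual
  and a relaxed (5×) gate for a track's first link — a plain
  nearest-neighbour 3 px gate cannot follow realistic conditions, where a
  66° sheet at 5 µm z-steps moves a bead ≈13.5 px between slices.  The
  y-skew is estimated empirically from the same fit rather than predicted
  from φ.
* **Sheet angle**: φ = 90° − arctan(shift/Δz), strictly decreasing in the
  shift; 2.2 µm per 5 µm step gives 66.25°.
* **Sheet dimensions** are principal-axis FWHMs from intensity second
  moments (so profiler images need not be axis-aligned), scaled by pixel
  pitch and demagnification.

## Reconstruction (`lsmkit.reconstruct`)

Pipeline order: import/ROI → de-skew → 3D deconvolution → background
thresholding → volume assembly.  Conventions: 0-based (row, col) = (y, x);
z grows with stage travel; user-facing ROI bounds are inclusive and
converted to half-open internally.

* **De-skew** translates slice k by −k·Δz·(sx, sy)/PI pixels with bilinear
  interpolation; vacated margins become NaN, which every downstream
  statistic excludes.  Bilinear shifting is a symmetric (tent-kernel)
  convolution, so spot centroids move by exactly the requested shift —
  the basis of the <0.1 px inversion guarantee.
* **Richardson–Lucy** uses frequency-domain convolutions with reflective
  padding, multiplicative updates clipped at zero, default 20 iterations,
  and an early stop when the relative update norm falls below 10⁻⁴.  RL is
  the named representative of the iterative-deconvolution family the
  pipeline calls for; the unit suite cross-checks it against an independent
  reference implementation on a small fixture.
* **Thresholding** computes per-tile mean + 3σ (NaN-aware), bilinearly
  interpolates the map between tile centres and subtracts, clipping at
  zero.  Tile statistics are *raw* — emitter pixels are not excluded — so
  the tile must be large relative to the features: a bright spot occupying
  a sizeable fraction of its own tile inflates the local σ and clips its
  flanks.  Default 16 px suits point-like emitters (2–3 px spots); the
  static bead analyses use 48 px tiles for ≈13 px bead images.  This is
  also why reconstructed bead diameters come out 15–28 % below truth
  (over-correction), mirroring how deconvolved bead data are reported in
  practice; the acceptance band is [−30 %, +15 %].
* **Volume assembly** attaches the physical scale (PI, PI, Δz) without
  resampling.  **Line sections** sample bilinearly and report the FWHM of
  the largest peak (half-crossings linearly interpolated), flagged
  undefined when no crossing exists on both sides.

## fcsSOFI (`lsmkit.dynamics`)

* **Correlator.** G(τ) = ⟨δF(t)δF(t+τ)⟩/⟨F⟩² evaluated *exactly* at each
  integer lag of a multi-tau (pseudo-logarithmic, 16/octave, capped at
  N/4) grid — sparse lag selection, no progressive binning — so the
  estimator agrees with a direct brute-force correlator to machine
  precision and is scale-invariant by construction.
* **Fit models.** 2D single-focal-area forms plus a free baseline:
  G₀/(1+τ/τ_D) + c, the two-component sum, and the anomalous form
  G₀/(1+(τ/τ_D)^α) + c.  The baseline is essential, not cosmetic: on a
  finite trace the sample-mean-subtracted correlation estimator is shifted
  down by ≈(2/T)∫G dτ, and without c the fitted τ_D is biased low by up to
  ~30 % at τ_D/T ≈ 0.016 (measured on simulated movies).  Weights are
  √samples-per-lag; initialisation G₀ = G(first lag), τ_D = half-amplitude
  lag; τ_D bounded to [frame interval, trace duration]; non-convergence is
  reported, never silently patched.
* **ω in D = ω²/(4τ_D).** For a Gaussian detection PSF of standard
  deviation σ, the pixel-intensity autocorrelation of freely diffusing
  emitters decays with τ_D = σ²/D, so the focal radius that makes the
  relation exact is the PSF's 1/e² radius ω = 2σ.  `focal_radius_omega_um`
  is defined as that 1/e² radius throughout, with converters
  `omega_from_sigma` (2σ) and `omega_from_fwhm` (2·FWHM/2.355).  Using σ
  itself would underestimate every D fourfold.
* **Pixel validity.** A pixel enters the diffusion map only if its trace
  has signal, its correlation actually decays (G at the longest lag below
  half of G at the first lag), its leading lags exceed 3× the tail
  standard deviation (rejecting white-noise pixels), the fit converges,
  and τ_D is not pinned within 1 % of its bounds.  Everything else is
  masked, never propagated.
* **SOFI.** Second-order correlation at one frame lag: native pixels carry
  their own AC; the interleaved (2×) grid places symmetrized
  cross-correlations of horizontal/vertical neighbour pairs at edge
  midpoints and diagonal-pair XC at cell centres.  Negative values are
  clamped to zero with the clamped fraction logged.  The exact virtual-
  pixel scheme (neighbour pairs, one-frame lag, no distance-factor
  correction) is this implementation's documented choice.
* **Fusion.** Hue is an affine map of log₁₀D clipped to a default range of
  0.1–100 µm²/s (blue slow → red fast; the endpoints are configurable),
  value is the SOFI image normalized to its 99.5th percentile, and
  saturation is zero on masked pixels so invalid regions render grey/black.

## Problem sizes

The test suite and acceptance script run on deliberately small instances:
24×24 px movies of 5000 frames (×4 per diffusion level), ≤200 px bead
frames, 9×33×33 deconvolution fixtures.  These sizes give per-quantity
statistical errors well inside the acceptance tolerances while keeping a
full run around one minute on a single CPU; all algorithms are
O(pixels·frames) or better and scale to full-frame data unchanged.

## Known limitations

* No vectorial/high-NA PSF models, aberrations, striping/shadowing, or
  rolling-shutter timing; lattice sheets are out of scope.
* The EMCCD model ignores clock-induced charge; the sCMOS model ignores
  pixel-dependent noise.
* Diffusion movies are 2D in-plane (a static sheet-depth weight stands in
  for the third dimension) and ignore photophysics and intra-frame blur.
* Theoretical sheet dimensions for a specific published instrument cannot
  be reproduced without its full lens table; the lens-train calculator is
  validated on closed-form single-lens arithmetic instead.
* Two figures reported for the reference instrument disagree (a 1.20 µm
  vs 1.44 µm depth of field); the implemented formula yields 1.20 µm with
  the stated parameters.
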