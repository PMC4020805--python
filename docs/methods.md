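# Methods

## Scope and model

`floralcam` recovers physically meaningful, linear reflectance measurements
from 8-bit UV/visible digital-camera frames. The measurement model has
three layers:

1. **Spectral forward model.** The linear response of channel *i* is
   `Q_i = ∫ S_i(λ)·E(λ)·R(λ) dλ` over the working wavelength grid. All
   integrals use trapezoidal quadrature; no integration rule is canonical
   for sampled spectra and the trapezoid at 1 nm agrees with 0.01 nm
   brute-force quadrature to better than 1 part in 10⁴ for spectra whose
   features are ≥ ~10 nm wide (asserted in the test suite). The default
   grid is 300–710 nm at 1 nm, covering a UV camera band (320–395 nm
   behind a UV-pass filter) and a visible band (400–710 nm) with margin.

2. **Camera nonlinearity.** The camera maps relative linear exposure
   `x ∈ [0, 1]` to a normalised pixel value through `q = a·e^{bx}`
   (single exponential) or `q = a·e^{bx} + c·e^{dx}` (biexponential).
   Real vendor tone curves are compressive (they brighten low signal), so
   a linearised frame is always darker than the raw frame — a property the
   tests assert for the shipped compressive profiles.

3. **Exposure standardisation.** Each frame carries achromatic standards
   of known flat reflectance. After linearisation, each channel is scaled
   independently so the standard reads its nominal value; frames are
   exposed so the brightest standard sits at pixel level 245 of 255,
   leaving headroom that keeps averaged responses free of clipped pixels.
   No software white balance is ever applied — per-channel calibration
   against a physical standard replaces it.

## Sensitivity fitting

Channel sensitivities are sums of one or two Gaussian terms
`a·exp(−((λ−b)/c)²)`. Fitting is nonlinear least squares (Levenberg–
Marquardt via `scipy.optimize.curve_fit`), initialised at the sample
argmax (centre), sample max (amplitude) and half the full-width-half-
maximum estimate (width); a second term is seeded at the largest residual
peak of the one-term fit. The two-term model is retained only when **all
six** coefficients are individually significant — their 95% confidence
intervals (t-based, from the least-squares covariance) exclude zero. Two
numerical guards matter in the degenerate noise-free regime, where the
covariance collapses to zero and every CI becomes a point:

- a term whose amplitude is below 10⁻⁶ of the largest amplitude is treated
  as non-significant (it carries a zero-width CI around an essentially
  zero value);
- for transfer functions, the richer model must also strictly improve the
  residual over the simpler one (parsimony tie-break), because a perfect
  single-exponential dataset can be fitted exactly by a degenerate split
  into two identical exponentials.

## Transfer fitting and LUT inversion

The characterisation series pairs relative exposure (log-spaced over
[0.02, 1], ≥ 6 steps spanning at least [0.05, 0.95]) with mean pixel
value. Candidate fits are rejected if non-monotonic on [0, 1] or outside
the physical range (`f(1) ≤ 1.05`; `f(0) ≥ −0.02` — a marginally negative
black offset is the normal outcome of an unconstrained fit to a noisy
series and is clamped to zero at inversion; rejecting it outright would
discard roughly half of legitimate noisy characterisations).

Inversion to the 256-entry LUT is numerical bisection (|f(x) − p/255| <
10⁻⁹, x clamped to [0, 1]) so one code path serves both functional forms;
the biexponential has no closed-form inverse. Pixel levels below the black
offset `f(0)` or above `f(1)` are clamped and flagged. Per-entry
uncertainty is the SD of the inverse over 1000 seeded draws of the
coefficients from independent normals matching their 95% CIs (draws
producing a non-monotone curve are discarded). A parametric bootstrap was
chosen over the delta method because the inverse is nonlinear and the
bootstrap needs no derivative bookkeeping at the clamp boundaries.

**Low-signal uncertainty.** For a monotone compressive transfer the
inverse is flat at the bottom of the curve, so the *absolute* bootstrap SD
is smallest at low pixel levels; what blows up there is the uncertainty
*relative to the recovered value* — at level 10 it is an order of
magnitude larger than at level 128 for the shipped profiles. The package
therefore stores the absolute SD per entry and exposes
`LinearLUT.relative_uncertainty`; the "low levels are noise-dominated"
contract is asserted on the relative quantity. Linear values below 9% of
the full-scale linear range (configurable) are flagged `low_signal`:
below that point responses are dominated by noise and follow a different
relationship than the fitted transfer.

## Reflectance recovery

`calibrate_exposure` derives one scale per channel:
`scale = nominal / mean(linear ROI)` per usable standard, combined across
standards by inverse-variance weighting (delta-method variance of the ROI
mean); a noise-free standard pins the scale exactly. Clipped (pixel
level > 245) and low-signal pixels are excluded from standard ROIs, and a
channel whose every standard is unusable is an error, not a silent
fallback. Values above 1 after scaling (super-white) are kept and visible
through the flags, never clamped. The choice of weighting rule across
multiple in-frame standards is a design decision of this package; common
practice uses whichever standard suits the band (spectralon in the UV,
checker white in the visible, the 33% grey in both) without stating a
combination rule.

`saturation_check` is an advisory diagnostic on the *non-linear* frame:
vendor firmware can boost a channel (saturated yellows/oranges) above the
response of a ≥ 90%-reflectance standard, which no physical reflectance
can produce; such regions are reported per channel, with
majority-clipped regions reported as clipped instead.

## Sampling statistics

Regions are squares: point samples of 15×15 px (225 px) at given centres,
or 3 cells drawn without replacement (seeded) from a 4×3 (scheme A,
default 40 px cells) or 6×2 (scheme B, 30 px) grid laid over a petal
bounding box. Pixel coordinates are 0-based, row-major, origin top-left.
Clipped/low-signal pixels are excluded from region statistics and counted.

Camera-vs-predicted comparisons use the two-sided Wilcoxon rank-sum test:
exact null distribution when the combined sample is ≤ 20 without ties,
normal approximation with continuity correction otherwise. By default the
camera side contributes one value per region (region means vs
spectrophotometer readings); a pooled per-pixel mode is provided. Results
are reported per channel without multiplicity correction, plus a
Holm-adjusted column flagged as an extension. Degenerate all-tied inputs
return p = 1 with an explicit warning. Shapiro–Wilk (3 ≤ n ≤ 5000) backs
the choice of a rank test; channel dispersion is summarised as the SD of
region means with a most-to-least-variable ranking (ties at 10⁻¹²).

## Synthetic fixtures

The generator defines the validation conditions:

- **Profiles.** Invented but realistic coefficients, labelled synthetic:
  three visible channels (Gaussian sensitivities centred 460/530/600 nm;
  the red channel carries a secondary 530 nm term) each with a distinct
  compressive biexponential transfer, and a UV channel (360 ± 25 nm) with
  a single-exponential transfer `0.05·e^{3x}` (black offset 0.05, as pure
  exponentials imply). Coefficient CIs are ±2%, standing in for a real
  characterisation's uncertainty.
- **Swatch frames.** Six flat swatches at 3.10, 9.11, 19.5, 37.2, 60.9,
  94.8% — the published reflectances of the Colour Checker neutral
  column — next to an ideal white standard exposed to exactly 245.
- **Grey ramps.** Log-spaced exposures through a known transfer, with
  optional multiplicative noise clipped at full scale (an 8-bit sensor
  cannot report above 255).
- **Flower scenes.** 512×512 canvas, disc flower sized so a scheme-A grid
  (160×120 px) fits inside the petal region; templates: plain,
  bullseye (UV-reflective petals, UV-absorbing centre — the floral-guide
  geometry), and a radial gradient. Petal spectra are 1–2 Gaussian bands
  plus a constant, imitating yellow and UV-reflective/absorbing classes.
- **Noise.** Zero-mean Gaussian read noise (default 1 intensity level)
  plus a shot term proportional to √signal (coefficient 0.5), applied to
  the linear signal before the nonlinearity and 8-bit quantisation.

What the fixtures do *not* emulate — and hence what passing tests do not
demonstrate about real data: optics (vignetting, PSF, chromatic
aberration), demosaicing, scene-dependent firmware processing, iridescence
and volume scattering, 3-D self-shading, illumination gradients across the
frame, and UV↔visible image registration. Real cameras also need their
transfer refitted per unit; the synthetic coefficients are not a
substitute for characterising an actual body/lens/filter combination.

## Numerical choices and edge cases

- Resampling is linear interpolation; outside the source support values
  are zero with a truncation warning, never extrapolated.
- The CIE daylight synthesis interpolates the 10 nm component tables
  linearly and normalises to 100 at 560 nm on the native table before
  regridding; the nominal CCT is multiplied by 1.4388/1.4380 by default
  (so 6500 K means ~6504 K, the convention under which the D65 tabulation
  was computed); a flag disables the correction.
- Reflectance spectra above 1.05 (brighter than the white standard) are
  tolerated and warned about, not clamped.
- `linearise_image` accepts only uint8 input — silently rescaling other
  bit depths would corrupt the radiometry.
- Clipping is `pixel > 245`: the calibrated white level 245 itself must
  stay valid, otherwise the exposure standard could never be measured.
- LUT entries are forced non-decreasing after bisection to absorb
  floating-point jitter at the clamp boundaries.

## Problem sizes

Validation runs use frames of 100×160 to 512×512 px, 16-step grey ramps,
100-replicate Monte-Carlo coverage studies for fitted coefficients and
1000-replicate null simulations for the rank test's type-I error; these
sizes give stable statistics while keeping the full suite fast.
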