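# Methods

## Bolus kinetics

Intravascular microbubble contrast follows a one-compartment pattern: the
agent never leaves the vessels, so a single indicator-dilution curve
describes the ROI enhancement.  We use the local density random walk (LDRW)
model

C(t) = (m/Q) e^λ √(λ/(2πμt)) · exp(−(λ/2)(t/μ + μ/t)),

where μ is the mean arrival time from injection to the detection site and λ
is a dimensionless diffusion parameter (large λ ⇒ narrow,
convection-dominated bolus).  C(0) = 0 (the analytic limit), C ≥ 0, the
curve is unimodal with its peak at t* = μ(−1+√(1+4λ²))/(2λ) — the positive
root of (λ/μ)t² + t − λμ = 0 — and its time integral is finite.  m and Q are
not separately identifiable from a TIC, so fits estimate the single
amplitude A = (m/Q)·scale and report it as such.

Default kinetics: λ = 2, μ = 30 s.  μ is chosen so the arterial phase of the
simulated liver acquisition peaks in the clinically typical 30–35 s window;
λ = 2 gives a washout that flattens by ≈90 s, comfortably inside a 200 s
acquisition.  These defaults define the study conditions of the sensitivity
experiments; they are plausible hepatic values, not a claim about any
specific dataset.

## Operational parameter definitions

Truth and measurement share one routine (`ceusdro.curves.curve_parameters`),
so relative errors isolate the acquisition chain:

* MI = peak enhancement above baseline; TTP = peak time from acquisition
  start (the configurable alternative — from bolus onset — is not used in
  the experiments).
* MTT = full width at half maximum of the baseline-subtracted curve
  (half-maximum crossings located by linear interpolation).
* Washout end = first post-peak time, after the curve has fallen below half
  maximum, where |slope| < 0.5% of MI per second.  A strict zero slope is
  reached only asymptotically; the tolerance makes the rule operational.
  The half-maximum guard prevents the rule from firing at the peak itself,
  where the slope also vanishes.
* AUC = trapezoidal integral of the enhancement from onset to washout end.
  Onset on model curves = 1%-of-MI upward crossing; on raw noisy TICs,
  baseline + 3 noise SD (noise SD estimated robustly from first
  differences).  A washout-only AUC (peak → washout end) is available as an
  option.
* upslope = MI/(TTP − onset), downslope = MI/(washout end − TTP),
  perfusion index = AUC/MTT.

Parameters are computed on the fitted LDRW curve (dense grid over [0, 50μ],
closed-form peak); if the fit fails they fall back to the smoothed raw
samples (moving average, window 5).  Fits start from a deterministic
initialisation (λ₀ = 1, μ₀ = observed TTP divided by the λ=1 peak fraction
0.618 so the initial model peaks at the observed TTP, baseline from
pre-onset samples, amplitude from the observed peak) and use bounded
least squares with an iteration cap.

## Measurement chain

Amplitude weighting per depth z: attenuation e^{−2zα}, α = 0.5 dB/cm/MHz ×
f, converted to nepers; a Gaussian axial focus profile (σ = 2 cm) centred at
the focus depth (4.5 cm, deliberately below the ROI, as is conventional in
perfusion imaging so the focus does not modulate the ROI amplitude); and
transmit pressure ∝ MI·√f (mechanical index fixed at 0.08).  The chain is
calibrated to unit weight at the vessel depth for the 1.5 MHz reference
acquisition, so frequency-sweep errors are minimal at 1.5 MHz; the default
vessel depth (2.9 cm) places the √f·e^{−2zα(f)} maximum there.  The full
A-line integral (pulse envelope with 60% fractional bandwidth, carrier
phase, trapezoidal depth quadrature) is exposed as a 1-D validation path;
frame synthesis applies the factorised per-depth weight pixel-wise — the
same attenuation/frequency physics at desk-scale runtime.

Log-compression uses the 20-dB exponent convention, which makes
linearisation its exact inverse before quantization (EP(QL(V)) = V²);
quantization is saturating (clip to [0,255]) with round-half-up, never
wraparound.  The round-trip amplitude error is bounded by one grey step,
(LC_DR/255)·(ln10/20) relative — at 60 dB about 2.7% per grey in power,
which ROI averaging and noise dithering reduce to far below a percent on a
TIC.  Receive gain multiplies amplitude before compression (standard
receive-gain convention; at 0 dB it is the identity, and low absolute gain
darkens the image by pushing the baseline toward the bottom of the window).

## Virtual phantom

Pixel echo **power** = tissue power + contrast_scale · C(t − delay), with
concentration mapping linearly to linearised intensity (echo power) — the
core proportionality assumption of TIC quantification; amplitude is its
square root.  Defaults: tissue power 4·10⁻⁴ of V_max² (baseline grey ≈174
at gain 15 dB / 60 dB), contrast peak ≈50× tissue power (≈17 dB enhancement,
peak grey ≈247 — below saturation across the sweep ranges at gain ≤ 15 dB).
The vessel is a single straight horizontal tube (radius 2 mm at 2.9 cm
depth); the parabolic Poiseuille profile v(ρ) = v_peak(1 − (ρ/r)²) enters as
an arrival-time dispersion delay(ρ) = τ(1/v_norm − 1) with centre transit
time τ = 0.5 s and the near-wall velocity floored at 0.1·v_peak, i.e. purely
temporal dispersion, no explicit displacement rendering.  Ground truth is
the centre-streamline curve measured with the rules above, computed upstream
of the measurement chain and therefore independent of acquisition settings,
seed and raster size.

**Noise.**  Zero-mean Gaussian noise of variance 0.3 is injected on the
8-bit grey-level scale of the stored frames (σ ≈ 0.55 grey levels), the
image-noise convention of computer-vision practice.  We deliberately do
*not* interpret the variance on the normalized [0,1] amplitude scale: there
σ ≈ 0.55 equals or exceeds any realisable echo amplitude, clipping at zero
rectifies the noise, and the ROI-mean linearised TIC becomes approximately
linear in amplitude rather than power — an analytically derivable distortion
(MI bias above +100%, MTT bias ≈ +7%) that would contradict the sub-2%
end-to-end uncertainties this chain is designed to exhibit at optimal
settings.  An amplitude-domain injection point (pre-compression, clipped at
zero) remains available via `PhantomSpec.noise_domain = "amplitude"` for
studying exactly that regime.  Grey-level noise also usefully dithers the
8-bit quantization before the ROI average.

Frame timing: 200 frames at 1 frame/s (200 s), covering arterial (~35 s),
portal (~120 s) and washout phases.  Fixture sizes share the physical field
of view (5.12 cm): `small` = 64×64×50 at 0.25 Hz (same 196 s span, coarser
sampling — builds in well under a second for tests), `medium` = 128×128×200
at 1 Hz, `full` = 512×512×200 at 1 Hz.

## Sensitivity experiments

Four sweeps: gain −20..20 dB step 1 (41 settings), dynamic range 30..90 dB
step 5 (13), gain × dynamic range as a seeded random subset of the 533-point
grid (default 50), and frequency 1..3 MHz step 0.5 (5) — 109 combinations in
total by default.  Each setting is evaluated on a shared set of noise seeds
(default 10) so settings are compared on identical realisations; per-point
failures become flagged rows rather than aborting the sweep.  Relative error
is the signed percentage (measured − truth)/truth × 100.  The optimum
minimises the unweighted mean of the four median |errors|, subject to a
clinical readability floor on gain (default 15 dB: very low gain minimises
error but yields images too dark to read; floor 0 disables the override).

Method comparison uses Pearson correlation (two-sided p), ordinary
least-squares regression, and Bland-Altman bias with limits of agreement
bias ± 1.96·SD of the paired differences.

## What the phantom does and does not emulate

It reproduces the parts of the chain that the sweeps probe: bolus kinetics,
depth/frequency-dependent amplitude, compression-window clipping,
quantization, and pixel noise.  It does not model speckle texture or
anatomical heterogeneity, nonlinear microbubble oscillation, respiratory
motion, recirculation, or multi-vessel trees.  Passing tests therefore
demonstrate correctness of the quantification chain under the stated model,
not robustness to in-vivo confounders such as motion or attenuation by
variable body habitus.

## Numerical choices and problem sizes

Truth and fitted curves are evaluated on 60 000-point grids over [0, 50μ]
(washout end, ≈90 s for the defaults, is found far inside the horizon).
Bounds for the fit: λ ∈ [10⁻³, 50], μ ∈ [10⁻², 10⁵], amplitude > 10⁻¹²,
with xtol = ftol = 10⁻¹⁴ and at most 2000 function evaluations.  "No bolus"
is declared when the smoothed prominence does not exceed
max(4·noise SD, 10⁻⁹ of the signal magnitude).  The end-to-end uncertainty
computation (tests and `scripts/acceptance.py`) uses the `medium`
128×128×200 fixture with 10 noise realisations — large enough that ROI
averaging (~500 px) makes the per-frame noise negligible, small enough to
run in seconds.

## Known limitations

* The AVI support is a minimal uncompressed 8-bit palettized DIB
  reader/writer; compressed AVI streams from scanners must be transcoded to
  uncompressed form (or TIFF) first.
* On the coarse `small` raster the ROI spans only ~3 vessel rows, leaving a
  systematic ≈0.9% amplitude-parameter bias from quantization and the
  row-weight mixture; the `medium` and `full` rasters reduce this below
  0.1%.
* The compressed-scale analysis mode fits the LDRW model to log-compressed
  grey levels, where the model is not the correct functional form; it is
  provided for comparison studies, not as a recommended analysis path.
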