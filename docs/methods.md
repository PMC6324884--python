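# Methods

This note documents the model implemented by `driftcsf`, the conventions and
defaults it commits to, what the synthetic drift generator does and does not
emulate, and the numerical choices that matter when interpreting its output.

## Model overview

The package predicts contrast sensitivity from a temporal-encoding
hypothesis: retinal ganglion cells (RGCs) are taken to be insensitive to
strictly unchanging stimuli, so all spatial information must arrive as
temporal modulation. Three stages:

1. **Retinal input.** A sinusoidal grating of spatial frequency `f`
   (cycles/deg), viewed through a moving eye with trajectory `ξ(t)`, is
   reconstructed as
   `I(x,t) = sin(2π f·(x − ξ(t)) + φ) · s(t) · M(t)`, with `s(t)` a
   sinusoidal contrast modulation at `ω_t` Hz (`s ≡ 1` for static
   gratings — the literal `sin(2π·0·t)` would null the stimulus, so
   `ω_t = 0` means unmodulated) and `M(t)` the trial's on/off contrast
   envelope. For a pure sinusoid the full space–time power spectrum reduces
   to the temporal spectrum of the complex demodulated signal
   `z(t) = exp(−i2πf·û(α)·ξ(t)/60)·s(t)·M(t)`; a brute-force 2D space–time
   FFT path is kept in the package as an equivalence oracle and agrees with
   the demodulation path to machine precision.
2. **Cell filters.** Space–time separable linear filters `K(f)·H(ω)`:
   a difference of Gaussians in spatial frequency and a cascade of `N`
   first-order low-pass stages plus one subtractive high-pass stage in
   temporal frequency, with published macaque parameter medians for magno
   (M) and parvo (P) cells shipped in `driftcsf/data/cell_params.yaml`.
3. **Readout.** Response power `O_ζ(f,ω) = P_I(f,ω)·|K_ζ(f)H_ζ(ω)|²` is
   integrated over temporal frequency (rectangle rule over the FFT bins, up
   to the 500 Hz Nyquist of the 1 kHz sampling; the filters decay several
   orders of magnitude before Nyquist, so the upper limit is immaterial).
   Sensitivity is the square root of that integral, and the combined
   prediction mixes the two classes linearly with weight `λ = 0.57` and a
   global gain `A`. `A` and `λ` only align the prediction with external
   data; they cannot change the curve's shape.

## Conventions and defaults

- **Diffusion coefficient.** Drift is 2D Brownian motion; `D` is in
  arcmin²/s with per-axis increment variance `2·D·Δt` (per-axis MSD
  `2·D·t`, planar MSD `4·D·t`) — the convention under which published
  fixational-drift estimates fall in the 100–350 range. The source
  literature does not pin the convention; every `D`-dependent quantity in
  the package (Lorentzian widths, scaling laws) uses this one consistently,
  so the factor-of-two ambiguity can only rescale the `D` axis, not change
  any shape or ordering. Under this convention the demodulated Brownian
  signal has autocovariance `exp(−k|τ|)` with `k = 4π²f²·D/3600`, i.e. a
  Lorentzian input spectrum with HWHM `k/2π` Hz (0.436 Hz at 1 cpd,
  D = 250).
- **Units.** Positions in arcmin, spatial frequency in cycles/deg
  (conversion by 60 at module boundaries), temporal frequency in Hz,
  filter time constants in ms (converted to seconds inside the
  dimensionless products `ρ·2π·ω·τ`).
- **Contrast envelope.** The trial envelope is not specified by the
  psychophysical sources beyond "smoothly ramped"; the default is a raised
  cosine of 0.5 s at each end of the 3.2 s trial. This choice matters: in
  the no-drift and strongly stabilized conditions the envelope is the
  dominant (or only) source of temporal power, so the absolute level — not
  the spatial-frequency dependence, which is flat — of those predictions
  depends on it. It is configurable (`EnvelopeSpec`).
- **Spectra.** One-sided PSDs with `P(ν) = |Z(ν)|² + |Z(−ν)|²` for `ν > 0`
  (the two signs carry the ±f spatial components of the real grating),
  normalized so that summed power × bin width equals the mean squared
  signal. No taper is applied by default — the envelope already acts as a
  window. The temporal resolution is 1/duration (0.3125 Hz for 3.2 s).
- **Sampling of the stimulus ensemble.** 8 orientations × 4 phases,
  100 trials per condition by default, 24 log-spaced spatial frequencies in
  0.1–60 cpd. Orientation averaging over a uniform grid implements the
  radial average of the circularly symmetric 2D spectrum. The spatial phase
  multiplies the demodulated signal by a unit constant and cancels exactly
  in power, so it is not looped over (recorded as metadata only).
- **Low-frequency policy.** The integral over temporal frequency starts at
  0.63 Hz by default: the cutoff is snapped to the nearest bin edge, so on
  the 3.2 s grid exactly the first two bins (0 and 0.3125 Hz) are
  discarded. The alternative `power_law` policy attenuates power below the
  cutoff as `(ν/cutoff)^exponent` (exponent 1 by default, emulating the
  approximately log-log-linear decline of measured low-frequency temporal
  sensitivity). Predictions for the drift condition are insensitive to this
  choice (peak shifts < 1% between 0.63 Hz, 1 Hz, and power-law variants),
  because drift-generated power lies well above 1 Hz at the frequencies
  that matter.
- **Shape descriptors.** Band-pass vs low-pass is operationalized as:
  low-pass iff sensitivity at the lowest sampled spatial frequency
  (0.1 cpd) is at least half the maximum (ties count as low-pass; threshold
  configurable). Peak location is refined by a parabolic fit to log
  sensitivity vs log spatial frequency through the grid argmax and its
  neighbors, to decouple reported peaks from the grid spacing.
- **Seeds.** All stochastic runs derive per-trace generators from a single
  root seed via `numpy` seed sequences; outputs record the seed and a
  config hash, and identical configurations reproduce byte-identical
  summaries.

## What the synthetic generator emulates — and what it does not

The study conditions this package emulates used recorded human eye traces,
which are not publicly deposited. The generator substitutes Brownian motion
with `D = 250` arcmin²/s for normal fixation and `D = 2` for retinal
stabilization. Brownian motion is a good statistical model of fixational
drift at these time scales, but it is not a recording:

- real drift is weakly mean-reverting over long fixations (bounded
  excursions), has subject-specific diffusion in the 100–350 range, and its
  velocity content is band-limited, whereas Brownian motion has white
  velocity and hence a heavy (ν⁻²) Lorentzian tail at high temporal
  frequencies;
- saccades, microsaccades, blinks, and tracker noise are absent by
  construction (the segmentation utilities exist to process user-supplied
  real traces, not the generator's output);
- consequently, tests passing on Brownian input show that the pipeline
  implements the model correctly and that its qualitative predictions
  (band-pass under drift, low-pass without, attenuation and peak shift
  under stabilization) are robust — they do not certify quantitative
  agreement with any individual observer's traces.

The Lorentzian tail matters quantitatively. With `D = 250`, the input
spectrum at the predicted peak (~5 cpd) has HWHM ≈ 11–14 Hz and substantial
power at 20–40 Hz, where the M-cell cascade (with the shipped
`τ_S = 2.23 ms`, a ~114 Hz high-pass corner under `ρ = 1/1.6`) has its
maximum gain. This M-pathway amplification holds the combined curve
band-pass up to flicker frequencies of ~9 Hz: the P-cell component turns
low-pass at 3 Hz, matching psychophysical reports of the band-pass→low-pass
transition, while the combined `λ = 0.57` mixture transitions near 9 Hz
rather than ~3 Hz. A physiologically slower M high-pass stage
(`τ_S ≈ 22 ms`) would move the static peak to ~4.6 cpd and the combined
transition to ~5 Hz; the package nevertheless ships the parameter values as
published and leaves them fully configurable rather than retuning them.

## Numerical choices and degenerate inputs

- FFT-bin rectangle integration everywhere; no interpolation across bins.
- The Lorentzian oracle offers alias-folded bin powers
  (`lorentzian_bin_power(..., aliased=True)`) for comparison with sampled
  spectra, since a sampled unit-modulus process keeps total power 1 while
  the continuous Lorentzian has a few percent of mass beyond Nyquist at
  high `sf·√D`.
- `D = 0` yields a motionless trace (valid, all power at DC); an all-zero
  CSF yields NaN descriptors flagged `undefined`; a non-monotone
  band-pass/low-pass classification along a flicker scan triggers a warning
  and returns the first crossing.
- DoG fitting works on log sensitivity with log-space parameters; a free
  overall gain fixes `Kc` to remove the scale degeneracy, so radii, `Ks/Kc`
  and the surround/center balance `Ks·rs²/(Kc·rc²)` are identified.
  Non-convergence is reported in the result object, not raised.
- Speed segmentation uses central differences and a 15 ms moving average
  (only the 2 deg/s threshold is prescribed by the sources). Note that raw
  Brownian traces exceed any fixed speed threshold with high probability as
  the sampling rate grows (white velocity), so segmentation is meaningful
  for real traces, not for the generator's output.

## Known limitations

- Linear, space–time separable filters only: no contrast gain control,
  nonlinear subunits, spiking, or eccentricity-dependent parameters beyond
  the single foveal scaling `γ = 0.5`.
- No optics (point-spread) or photoreceptor sampling/noise; predictions at
  very high spatial frequencies (> 40 cpd) should not be taken literally.
- Sinusoidal gratings only; arbitrary images are out of scope.
- The absolute scale of predicted sensitivity is arbitrary (the global gain
  `A` is free); only shapes, ratios, and orderings are meaningful.
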