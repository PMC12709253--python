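# Methods

## Beat model and representations

The pipeline treats a beating axoneme as a planar inextensible filament.
Each frame is an ordered set of midline coordinates (μm, base first); all
analysis happens in the tangent-angle representation ψ(s, t), the angle of
the local tangent versus arc length s, on a regular (s, t) grid. Curvature
is ∂ψ/∂s, so a circular arc is a straight line in ψ–s space and a
traveling bending wave is a propagating oscillation of ψ.

The working model of the beat, which the synthetic generator produces and
the validation battery assumes, is

ψ(s, t) = C₀·s + a·sin(2πs/λ₀ − 2πft + φ) + η(s, t) ,

with static curvature C₀ (rad/μm), tangent-angle amplitude a (rad),
wavelength λ₀ (μm), frequency f (Hz), and i.i.d. uniform angle noise η on
±(noise_level·a). For the Cartesian shape, the swimming frame's rigid-body
rotation Ωt is added to ψ before integration, x(s) = ∫cos(ψ+Ωt)ds,
y(s) = ∫sin(ψ+Ωt)ds (cumulative trapezoid), with the basal point at the
origin. Rigid-body *translation* is not modeled: every analysis stage works
on shape (tangent angles), which translation cannot affect. The arc-length
grid uses the nearest whole number of samples, so it spans L to within half
a sample, like a pixel grid covering a tracked filament.

Real beats may have amplitude profiles that taper toward the base; the
generator defaults to uniform amplitude and exposes a linear `amplitude_taper`
for sensitivity studies, since no measured profile constrains it.

## Pipeline stages

1. **Geometry.** Per frame: chordal arc length, cubic-spline resampling of
   x(s), y(s) at ds = 0.218 μm (the effective pixel size of the targeted
   recordings), tangent angle from central differences (second-order
   one-sided at the ends), unwrapped along s. Frames with fewer than 4
   points are rejected with a warning; frames whose length deviates more
   than 5% from the median are flagged as probable tracking failures (the
   threshold is configurable; nothing in the data fixes it).
2. **Rotation removal.** The leading tangent angle ψ(0, t) is unwrapped in
   time and LOESS-smoothed; the trend is subtracted from ψ(s, t) at all s
   (a per-frame scalar, so shape is untouched). The default span covers 5
   beat periods, using a provisional FFT of the leading angle for the
   period: wide enough that the oscillation averages out, narrow enough to
   follow slow rate drift. The rotation rate is the trend's interior slope
   (the outer 10% of frames are excluded from the rate fit — LOESS is
   biased at the record boundaries).
3. **Segmentation and decomposition.** Frames are cut into consecutive
   windows of round(1/(f·dt)) frames; the trailing partial window is
   dropped. The static component ψ̄(s) is the time average over complete
   windows only (a partial cycle would bias it); the static curvature C₀
   is the OLS slope of ψ̄(s) vs s; ψ_d = ψ − ψ̄ reconstructs the field to
   machine precision (~1e-16 rad; exact reconstruction holds only in exact
   arithmetic).
4. **Wavelength.** For each beat window, G_ψ(k, t) (trapezoid quadrature of
   the two Fourier integrals) is averaged over the window's frames and the
   argmax over k is located on a 2048-point uniform grid spanning
   k ∈ [2π/(2L), 2π/(L/4)] — wavelengths between a quarter and twice the
   axonemal length — then refined with a three-point parabola. The grid
   density is a numerical choice: with refinement, discretization error is
   far below the estimator's 1% systematic-error budget. Per-beat
   wavelengths are averaged; their SEM is the reported precision. A peak on
   the search boundary is flagged (the true wavelength may lie outside the
   range). An "all_frames" mode averages G over the whole record and takes
   a single argmax — the estimator's defining formula — and agrees with the
   per-beat default to <0.5% on clean fields. No taper/window function is
   applied to the integrals.
5. **Kinematics.** Frequency: temporal power spectra of ψ_d averaged over
   s; dominant non-DC peak refined by a parabola in log power (skipped when
   the neighbor bins are pure leakage noise, so an on-grid tone is returned
   exactly); errors are raised for DC (no oscillation) or Nyquist
   (undersampled) peaks. Velocity: zero crossings of ψ_d(s) per frame by
   sign change + linear interpolation, linked across frames by nearest
   neighbor within a gate (three times the median per-frame displacement
   from a generous-gate first pass, floored at two grid steps); tracks
   shorter than 3 frames are discarded; the velocity is the mean
   least-squares s-vs-t slope over all tracks in the analyzed window.
6. **Statistics.** Two length–wavelength datasets are compared by
   interpolating one linearly over length as a reference curve, reducing
   the other's in-range points to residual signs ordered by length, and
   counting sign changes n among the N points; t = |n − N/2|/(√N/2) with
   N/2 degrees of freedom (rounded down), two-sided p, Bonferroni for
   families. An exactly-zero residual inherits the previous sign and is
   flagged. Regression slopes are "significant" iff |m| ≥ 2·SE(m). The SE
   follows the binomial-scale √N/2; under null simulation the test's
   type-I error at α = 0.05 is 5–6.5%, the crossing count's mean sits
   within ~1.5 crossings of N/2 (it is depressed below N/2 both by the
   n ≤ N−1 ceiling and by reference-noise sharing between neighboring
   residuals) and its SD within ~10% of √N/2 — the calibration that
   justifies the t-approximation at this sample-size scale.
7. **Mechanics.** Ma = fξ⊥λ⁴/(8π³κ), F/L = 2π²(ξ⊥−ξ∥)fy₀²/λ, v = F/(Lξ∥).
   Drag coefficients and flexural rigidity are user inputs; the example
   driver carries literature-typical magnitudes (ξ∥ ≈ 0.0017 pN·s/μm²,
   ξ⊥ ≈ 2ξ∥, κ ≈ 400 pN·μm²) that are placeholders, not measurements.

## Estimator accuracy and validation

For a sinusoidal traveling wave observed over a finite window, the
beat-averaged spectrum has the closed form
⟨G⟩(k) = a²/2·(|∫cos(k₀s)e^{iks}ds|² + |∫sin(k₀s)e^{iks}ds|²) (integrals
over the analyzed window), a sinc-type function whose peak coincides with
k₀ when the window is an integer number of wavelengths and is displaced by
a finite-window term otherwise. The validation battery
(`axobeat validate`, `analysis/04`) measures:

* **Bias:** |λ̂ − λ₀|/λ₀ < 1% for every L/λ₀ ≥ 1 on the standard grid
  (measured ≤ 0.1%); at L/λ₀ = 0.5 the window is half a wavelength and the
  error is reported, not asserted — the useful domain is λ ≤ 2L·(1/2),
  i.e. window at least half a wavelength and preferably a full one.
* **Noise robustness:** with ±50% uniform angle noise the record-averaged
  peak moves by less than one k-grid step. The peak's noise jitter scales
  with the arc-sampling step: at 0.218 μm sampling it is itself of order
  one grid step (≈0.02 μm, 0.2% of λ — far inside the estimator's 2% noise
  tolerance), so this check runs on a finely sampled (0.05 μm) simulated
  field where quadrature jitter does not confound the comparison.
* **Analytic overlay:** the closed form matches dense quadrature to ~1e-14
  of the spectral peak, and its argmax coincides with the numerical
  estimator's within one grid step.

A single frame's spectrum peak carries a phase-dependent displacement of
order 1/(k₀L); beat averaging is what removes it, which is why per-beat
(or record) averaging precedes the argmax.

An optional `trim_fraction` restricts integration to the middle of the
axoneme (0.1 → middle 80%) for digitized microscopy data, whose endpoint
tangents are least reliable. On clean fields the trim shortens the window
and reintroduces ~2% finite-window bias in the λ₀ ≈ L regime, so it
defaults to 0 and the validation battery runs untrimmed; the wavenumber
search range always uses the full length L.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analysis assumes —
a single-wavelength sinusoidal traveling wave on a static arc, stationary
in frequency and amplitude, with white angle noise and optional Cartesian
jitter. Real beats are asymmetric, anharmonic, amplitude-modulated along
the axoneme, and their digitization errors are correlated along the
filament. Passing the parameter-recovery and cross-method suites therefore
demonstrates the correctness of the implementation and the estimator's
finite-window behavior, not the fidelity of the sinusoidal model to real
waveforms; on real data the per-beat SEM and the Fourier-vs-v/f comparison
are the internal consistency checks.

## Problem sizes and determinism

Validation and tests use the study-scale conditions throughout: 0.218 μm
arc sampling, 1000 frames at 1 ms, lengths 8–25 μm, 65 Hz beats, ±50%
uniform noise for stress tests, 50 replicates for the variance comparison
between λ̂ and v/f, and 1000 null replicates (N = 16 points per dataset,
noise SD 1 μm around the saturating curve) for the crossing-test
calibration. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical parameters and seed give
bit-identical fields and byte-identical reports.

## Known limitations

* The tangent-angle endpoint estimates use one-sided differences; nothing
  constrains the true endpoint behavior of tracked data.
* Zero-crossing velocimetry assumes a predominantly traveling wave; for
  standing-wave-like beats it correctly reports v ≈ 0, and λ = v/f is then
  meaningless (the Fourier estimator remains defined).
* The crossing test's reference-curve interpolation is one reading of
  "data crossing data"; it is validated against its own null calibration,
  not against a published algorithm.
* Wavelength drift within a record is averaged over, not tracked; there is
  no time-frequency analysis.
* 3-D shapes, image processing and filament tracking are out of scope: the
  pipeline starts at digitized centerline coordinates.
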