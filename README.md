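# axobeat

Quantification of the flagellar/ciliary beat from digitized axoneme
centerlines: tangent-angle decomposition, a finite-window Fourier estimator
of the beat wavelength, beat frequency and zero-crossing wave velocimetry,
and nonparametric comparison of length–wavelength relations between
preparations.

## The problem

Isolated, reactivated *Chlamydomonas* axonemes beat at ~65 Hz and swim in
circles. High-speed phase-contrast recordings (1000 frames in 1 s, 0.218 μm
effective pixel size) are digitized into per-frame midline coordinates, from
which one wants the quantities that characterize the beat: the wavelength λ
of the traveling bending wave, the beat frequency f, the wave velocity v,
and the static curvature C₀ of the mean shape. The central difficulty is
that an axoneme supports only one-to-two wavelengths over its 8–25 μm
length, so λ must be estimated from a window comparable to λ itself —
the regime where naive spectral peak-picking is badly biased.

## The method

Every frame's shape is reduced to the tangent angle ψ(s, t) versus arc
length s. The slow rigid-body rotation of the circling swimmer is a LOESS
trend of the leading tangent angle ψ(0, t), subtracted frame-wise. The
rotation-free field splits into a static component ψ̄(s) (time average over
complete beat cycles; its slope is C₀) and the dynamic beat
ψ_d(s, t) = ψ(s, t) − ψ̄(s).

The wavenumber of the dynamic beat is estimated from the finite-window
spatial power spectrum

    G_ψ(k, t) = ( ∫ ψ_d(s,t) cos(ks) ds )² + ( ∫ ψ_d(s,t) sin(ks) ds )²,

averaged within each beat cycle; the argmax over k — restricted to
wavelengths between a quarter and twice the axonemal length and refined by
a three-point parabola — gives one wavelength per beat, and the per-beat
values are averaged (λ̂ ± SEM, k̂₀ = 2π/λ̂). For a sinusoidal traveling
wave the beat-averaged spectrum has a closed form (implemented as
`analytic_G`), the estimator is unbiased at λ = L, and its systematic error
stays below 1% whenever λ ≤ L. Beat frequency comes from the temporal DFT
of ψ_d with parabolic peak interpolation; wave velocity from linked
zero-crossing tracks of ψ_d(s), so λ = v/f cross-validates the Fourier
estimate. Length–wavelength curves of two preparations are compared with a
zero-crossing sign test (t = |n − N/2| / (√N/2), df = N/2, Bonferroni
corrected), and closed-form low-Reynolds-number quantities (Machin number,
propulsive force per length, swimming speed) are provided.

A synthetic generator produces traveling-wave beats
ψ(s,t) = C₀s + a·sin(2πs/λ₀ − 2πft + φ) with rotation, uniform angle noise
and Cartesian jitter, so the whole pipeline is testable without microscopy
data.

## Worked example

```
axobeat simulate --length 10 --wavelength 10 --seed 1 --out axo.csv
axobeat analyze axo.csv --out report.json
```

prints

```
L=10.03 μm  λ=10.02±0.00 μm  f=65.00 Hz  v=648.9 μm/s  C0=-0.000 rad/μm  (66 beats)
```

i.e. on a clean synthetic beat with λ₀ = L = 10 μm at 65 Hz the pipeline
recovers the wavelength to well under 1%, the frequency to the DFT-bin
refinement limit, and v ≈ fλ. The same stages are available as library
calls (`analyze`, `estimate_wavelength`, `beat_kinematics`, ...), and the
numbered drivers under `analysis/` run the full study on a simulated
cohort: `01` simulates two preparations spanning 8–25 μm with the
saturating law λ₀ = min(L, 15 μm), `02` analyzes them, `03` shows the
proportional (slope 0.998 ± 0.000, significant) versus saturated
(slope 0.009 ± 0.008, not significant) regimes, `04` regenerates the
estimator validation battery, `05` finds no significant difference between
the two preparations (n = 1 of N = 6, p = 0.20), and `06` evaluates the
mechanics closed forms.

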