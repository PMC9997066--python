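# Methods

This note records the models implemented in `rmakit`, the assumptions they
make, the defaults and why, and what the synthetic benchmarks do and do not
demonstrate.

## Stepped-cantilever modal model

A width-stepped cantilever is treated as a one-dimensional two-segment
Euler–Bernoulli beam: segment 1 (root, length `l_n`) lumps the
`n_support_beams` narrow beams into one equivalent member by summing their
mass per length and flexural rigidity; segment 2 is the wide plate.
Boundary conditions: clamped root (`W=W'=0`), continuity of displacement,
slope, bending moment `EI·W''` and shear `EI·W'''` at the step, free tip
(`W''=W'''=0`).  With the general `sin/cos/sinh/cosh` solution per segment
this yields an 8×8 homogeneous system; eigenfrequencies are the roots of
its determinant in `ω`.

Numerics: the determinant is scanned on a 2000-point log grid (1 Hz–50 kHz
by default) and each sign change is refined by Brent's method to 1e-12
relative; rows of the boundary matrix are rescaled to unit max-abs so the
hyperbolic terms cannot swamp the determinant; mode shapes come from the
SVD null vector, with the smallest-singular-value ratio checked (< 1e-6)
as an ill-conditioning guard.  The solver is verified in the test suite
against (a) the uniform clamped-free closed form
`f_k = λ_k²/2π·√(EI/(mL⁴))` in the equal-segment limit (< 1e-6 relative)
and (b) an independent Hermite-element FEM eigensolver on the reference
geometries (< 2e-3 relative).

**Composite narrow segment (default).**  The electrode/insulator/piezo
stack (Al 0.2 µm / SiN 0.1 µm / ZnO 0.5 µm / SiN 0.1 µm / Al 0.2 µm) sits
only on the narrow support beams; the plate is bare 5 µm device-layer Si.
Segment properties therefore come from a transformed-section calculation
about the composite neutral axis for segment 1 and from the single Si
layer for segment 2 — this is why the governing equations carry distinct
`E₁I₁` and `E₂I₂`.  With Si (110) constants (E = 169 GPa, ρ = 2329 kg/m³)
and standard thin-film handbook values (Al 70 GPa / 2700; PECVD SiN
250 GPa / 3100; sputtered ZnO 140 GPa / 5606, d31 = 5.43 pC/N, ε_r = 10.9)
the eight reference fundamentals land 1–5% above the quoted design
frequencies.  A pure-Si simplification (`presets.silicon_only_layers`) is
available but sits ~18–21% low: the stack's stiffening of the hinge is not
negligible.  The stack raises the narrow segment's per-width rigidity by
×1.67 and its mass by ×1.39.

What the 1-D model cannot do: distinguish rocking/torsional modes of
centre-beam vs edge-beam layouts (a genuinely 2-D effect), or predict
absolute static stress fields.  Second-mode frequencies are reported but
only the bending branch is meant.

## Mel grid

Channel frequencies are uniform in the HTK Mel scale
`m = 2595·log₁₀(1 + f/700)`; this convention was adopted because the
reference array's eight quoted frequencies are uniform in it to ±1 Hz
(all seven Mel gaps ≈ 63.9).  Grid endpoints default to the realised
design span (253, 717 Hz); the nominal wheeze band (200, 800 Hz) is kept
in the packaged config as an alternative.  Rounding to integer Hz matches
how design frequencies are quoted; the rounded grid reproduces all eight
reference values within 1 Hz (two of them — 309 vs 308 and 430 vs 429 —
differ by exactly 1 Hz, i.e. the quoted table was rounded from a slightly
different anchor).

## Root stress and piezo voltage

`estimate_root_stress` is deliberately the crudest statics model: the
plate is rigid, the total force `p·l·c` acts at the area centroid, the
root moment is shared equally by the support beams, and the beam-root
bending stress is `M·(h/2)/(c_n h³/12)`.  Only stress *ratios* between
geometries are claimed (stepped vs plain cantilever ≈ 5×, consistent with
elastic FEA ratios); absolute values are not.  The open-circuit voltage
`V = σ·d31·t/(ε₀ε_r)` is the plate-capacitor charge model — film area
cancels, leaving thickness only.

## Resonator and noise model

Each channel is the second-order magnitude response
`|H(f)| = S_peak·(f₀²/Q)/√((f₀²−f²)² + (f·f₀/Q)²)`, anchored so
`|H(f₀)| = S_peak` exactly (measured sensitivities are quoted at
resonance); the DC sensitivity is `S_peak/Q`.  Note two O(1/Q²) facts used
by the tests: the magnitude peak sits at `f₀√(1−1/(2Q²))`, and the
operational Q (peak over −3 dB bandwidth) deviates from the pole Q by ~2%
at Q = 5.  The digital realisation is the bilinear transform of the analog
prototype, pre-warped at f₀ so the tone gain at f₀ is exact; fs defaults
to 4 kHz (the 200–800 Hz band with margin).  Phase is not asserted
anywhere; only magnitudes are.

The default eight-channel fixture anchors the four printed end-point
measurements: Q rises linearly with f₀ from 13.5 to 22 (small cantilevers
are less air-damped) and S_peak falls log-linearly from 265 to 86 mV/Pa.
Per-channel measured values were not published; the fixture is an
interpolation, not data.

Noise arithmetic: noise floor in Pa = input-referred RMS noise voltage /
sensitivity; in dB re 20 µPa via `20·log₁₀(p/2·10⁻⁵)`; SNR at 1 Pa =
94 dB − noise floor (93.98 dB exactly; 94 is the conventional rounding).
A-weighting is the IEC 61672 rational form, normalised to 0 dB at 1 kHz.
With the printed best-case anchors (3 µV A-weighted, 265 mV/Pa) the chain
gives 98.9 dBA.  Electrical crosstalk, amplifier circuit behaviour beyond
the scalar gain 101, and 1/f noise spectra are out of scope.

## Synthetic lung-sound generator

The generator emulates exactly one property of annotated respiratory-sound
corpora: wheeze recordings carry elevated narrowband power, concentrated
roughly in 300–600 Hz, on top of broadband breath noise; normal recordings
are broadband only.

* Breath: Gaussian noise band-limited to 100–1000 Hz (4th-order
  Butterworth), shaped by a per-cycle raised-cosine inspiration/expiration
  envelope; 2.5 s cycle, inspiration fraction 0.4 (typical adult
  breathing), RMS 0.15 full scale.
* Envelope floor: the raised-cosine bumps sit on a constant pedestal
  (`base_level = 0.6`, i.e. 40% amplitude modulation).  Chest-wall lung
  sounds are a continuous murmur, not gated silence; without the pedestal,
  frame log-energies carry several log-units of common-mode level variance
  that swamps the spectral contrast for a naive-Bayes frame classifier.
  The default was set so the generator meets its design calibration
  (separable classes at +6 dB, chance at −∞; see below).
* Wheeze: a sinusoid whose frequency drifts slowly (±20 Hz, one wander per
  ~4 s) around a per-recording centre drawn from 300–600 Hz, plus a second
  harmonic at −10 dB, amplitude-following the breath envelope.  By default
  it spans both respiratory phases (severe-obstruction wheezes are
  biphasic); `phases=("expiration",)` restricts it, and `duty` trims each
  gated phase.  The tone is scaled to a wheeze-to-breath power ratio of
  +6 dB over the gated samples; `-inf` disables it, making the classes
  statistically identical.  Peaks are renormalised (never hard-clipped).
* Determinism: a master seed fans out to per-recording child seeds; two
  runs with the same seed produce bit-identical waveforms and manifests.

What passing tests show — and do not.  The calibration is prescribed, not
emergent: at +6 dB the classes are separable (array energies + GNB reach
≥ 0.95 frame accuracy), at −∞ dB accuracy is at chance.  The generator has
no crackles, no playback/re-recording acoustics, no microphone self-noise,
no inter-patient variability; results on it demonstrate that the pipeline
is correct and that the acoustic feature path carries the same information
as the digital one, not that any accuracy level transfers to clinical
recordings.

## Features and classification

Frames are 40 ms, non-overlapping, rectangular-windowed by default (a Hann
flag exists); trailing partial frames are dropped.  The acoustic route
computes `log(ΣX² + 1e-12)` per channel per frame — no transform.  The
digital route computes a magnitude-squared FFT (zero-padded to the next
power of two) through unit-peak triangular filters whose centres are
Mel-uniform across the band, outer triangles clipped at the band edges;
adjacent unit-peak triangles tile the interior with exactly unit coverage,
so total filterbank output equals in-band spectral energy.  Log
compression keeps the Gaussian class-conditional assumption of the naive
Bayes plausible; MFCC/DCT is deliberately not implemented.

The Gaussian naive Bayes is fitted in closed form (per-class ML mean and
variance per dimension, priors from frequencies, variance floored at
1e-9 × the largest pooled variance); prediction is the log-posterior
argmax with ties broken toward the larger prior, then the
lexicographically first class.  The SVM contract (linear kernel, C = 1,
features standardised with training-set statistics only) is delegated to
scikit-learn.  Splits are always at the recording level — all frames of a
recording stay on one side — because frame-level splits would leak nearly
identical neighbouring frames between train and test; metrics are pooled
over test frames.

Benchmark problem sizes: the packaged experiments use 50 recordings
(25/25) of 2 breath cycles (5 s) at 4 kHz — 125 frames per recording,
6250 frames total — with dataset seed 7; unit tests use 24 recordings.
At these sizes the full suite runs in a few seconds.  On matched synthetic
data the 8-channel acoustic route scores within ~0.02 of the 8-filter
digital route (5-fold means 0.961 vs 0.974); the margin moves by about
±0.01 across dataset seeds.

## Known limitations

* The beam model is 1-D: no torsion, no anticlastic plate stiffening, no
  residual-stress warpage; measured devices resonate below design values
  for fabrication reasons (thinner Si) the model does not know about.
* The stress model is for ratios only.
* The resonator model is minimum-phase second-order; measured sensitivity
  curves carry crosstalk ripples that are not modelled.
* The synthetic corpus is a stand-in, uncalibrated against any clinical
  dataset; absolute classification numbers on it are properties of the
  generator settings.
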