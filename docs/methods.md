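# Methods

## Problem and model

`respiradar` simulates and analyses non-contact respiration monitoring with
a 77 GHz FMCW radar. A chirp of bandwidth *B* = 4 GHz and duration
*T* = 50 µs is mixed with its echo from a reflector at range *R*, giving a
dechirped IF sample

    s(t) = A · exp(−j(2π·fc·td + 2π·(B/T)·t·td − π·(B/T)·td²)),   td = 2R/c,

a beat tone at frequency (B/T)·td whose constant term 2π·fc·td makes the
phase of the tone a displacement sensor with sensitivity 4π/λ radians per
metre (λ = c/fc ≈ 3.9 mm). Chest-wall breathing motion is modelled as a
repeated arch

    xr(t) = Ar · (0.5 − sin^p(π·fr·t'))  on one period t' ∈ [0, 1/fr],

with amplitude *Ar*, rate *fr* and shape exponent *p*. For *p* = 2 this is
exactly (Ar/2)·cos(2π·fr·t). During apnoea intervals (meningitic
breathing) the *breathing clock pauses*: the chest holds its onset
position and the cycle resumes continuously, so breath-holds neither jump
nor teleport the chest.

## Simulator

`synthesize_cube` evaluates the IF model per chirp with the chest
quasi-static over one 50 µs chirp (respiration is 6 orders of magnitude
slower). A scene adds strictly stationary point clutter, complex circular
Gaussian receiver noise calibrated so the per-sample target-echo SNR
equals `snr_db`, and an uncalibrated 4-channel receiver: per-channel
constant phase offsets (drawn uniformly from (−π, π] when unspecified) and
optional integer slow-time lags. All randomness flows from a single seed.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| Ar (normal) | 4 mm | resting adult chest-wall excursion is a few mm |
| fr (normal) | 0.20–0.33 Hz | resting adult band, 12–20 breaths/min |
| p | 2 (presets jitter 1.6–2.6) | rounded peaks; p=2 is exactly sinusoidal |
| slow/deep | fr 0.10–0.15 Hz, Ar ×1.5–2.5 | deeper breathing, larger excursion |
| quick | fr 0.40–0.50 Hz, Ar ×0.6–1.0 | rapid shallow breathing |
| meningitic | normal + apnoea 4–8 s every 10–15 s | alternating breathing/breath-hold |
| record length | 25 s (500 frames at 50 ms) | standard collection window |

What the generator does *not* emulate: heartbeat, gross body motion,
multipath, antenna patterns, clothing attenuation. Passing tests therefore
show the chain is correct under its stated physics, not that it is robust
to every real-world disturbance.

## Processing chain

1. **Range FFT** over fast time. The IF model carries `exp(−j·)` phase, so
   samples are conjugated first; a target at range R then lands in bin
   R/(c/2B) of the positive-frequency half and its phase *increases* with
   range (the 4π/λ convention).
2. **Bin selection**: maximum time-averaged magnitude inside a 0.3–2.0 m
   window (covers the tested subject distances); ties break toward the
   nearer bin. The window assumes the breathing subject is the dominant
   in-window reflector.
3. **Phase chain**: wrapped bin phase → cumulative ±2π unwrapping
   (standard rule; symmetric and subsumes one-sided 2π subtraction) →
   backward difference d(t) − d(t−1), which removes constant phase drift
   exactly.
4. **Channel combining** (before phase extraction — IQ summation of
   wrapped per-channel phases is ill-defined, so complex-domain combining
   is done first and one phase is extracted from the sum):
   * *overlay* (default): per-channel static-phasor (time-mean) removal,
     then integer-lag alignment (±5 samples, via the peak of the complex
     cross-correlation against channel 0) and rotation by the conjugate
     correlation phase, then coherent summation. Noise grows √K, signal K.
   * *apc*: the same static-phasor removal but a plain unaligned channel
     average — partial noise attenuation only.
   * *mti*: single-delay canceller y[k] = x[k] − x[k−1] on the channel
     average — exact static rejection at the cost of spectral shaping.
   * *raw*: channel 0 untouched.
5. **Motion gate**: if the selected bin's fluctuating power is below 1% of
   its static power there is no moving target (empty scene or
   breath-hold) and the waveform is reported as zero. Without the gate the
   phase of a noise-only residual would read as full-scale noise however
   high the SNR.
6. **Band-limiting**: elliptic (Cauer) bandpass 0.1–0.5 Hz, order 4,
   0.5 dB passband ripple, 40 dB stopband attenuation, applied
   forward-backward for zero phase; then a centred 0.5 s moving average.
   The elliptic family gives the sharpest transition for a given order;
   the order/ripple values are package choices (only the band is
   physiologically fixed).
7. **Spectral estimate**: Hann-windowed periodogram zero-padded to a
   ≤ 2 mHz grid, peak within 0.1–0.5 Hz refined by parabolic
   interpolation on the log magnitude; flagged (NaN) when the in-band
   peak falls below 5% of the global spectral maximum.

### Beat-referenced phase (`precise_phase`)

The plain FFT-peak phase of a dechirped tone contains two artefacts
besides 2π·fc·td: the off-grid (Dirichlet) phase of the tone, equivalent
to sensing at the chirp *centre* frequency (a ≈ B/2fc ≈ 2.6% slope
offset), and the residual video phase −π·(B/T)·td². `precise_phase`
removes both by refining each frame's beat frequency to its exact
fractional-bin position (bounded search plus a derivative root-polish)
and adding back the predicted RVP. For a noiseless single reflector the
result equals 4π·R(t)/λ to machine precision; the main pipeline keeps the
plain bin phase, where a 2.6% amplitude scale is irrelevant.

## Breath counting

Waveforms are normalised to max |v| = 1. Candidate events are strict
three-point local extrema (plateaus collapse to their midpoint) with
|value| > 0.2 — the threshold excludes inconspicuous ripples. The event
scan discards a leading trough, collapses repeated peaks to the first
pending one, closes one breath per trough following a pending peak, and
discards a trailing unpaired peak. Rates come from three estimators —
60·count/duration, 60·(spectral peak), and 60/(first significant
autocorrelation period beyond 2 s, normalised autocorrelation > 0.2) —
which agree within 2 bpm on clean signals.

## Features and classification

Normalised waveforms are drawn as deterministic 256 × 256 grayscale
images (fixed y-limits ±1.1, 2 px dark polyline on white, 4× supersampled
then box-downsampled; the style is frozen so descriptors are reproducible
bit-for-bit). HOG uses centred-difference gradients with replicated
borders, magnitude G = √(Gx² + Gy²) and unsigned orientation
atan2(Gy, Gx) mod 180°; 9 orientation bins per 8 × 8 cell with circular
bilinear vote-splitting between adjacent bin centres; 2 × 2-cell blocks at
1-cell stride, each block L2-normalised (ε = 1e-12, so a constant image
maps to the zero vector). On 256 × 256 the descriptor has
31·31·4·9 = 34 596 entries. PCA centres the descriptors and keeps
components reaching 95% cumulative variance (capped at n−1); it is fitted
on the full descriptor set before cross-validation — PCA is unsupervised,
so this leaks no label information.

Classification is one-vs-one over the 6 class pairs with binary
soft-margin SVMs (linear kernel, C = 1 — the formulation is linear and
the features high-dimensional; RBF is exposed as an option). Vote ties
break by accumulated decision-function confidence. Each binary machine's
dual solution is checked against the KKT conditions (αᵢ ≥ 0, Σαᵢyᵢ = 0,
margin violations only at the C bound). The KNN baseline uses Euclidean
distance, k = 5, vote ties broken by the nearest neighbour among the tied
classes. Evaluation is stratified fivefold cross-validation (4:1
train:test), seeded.

## Numerical and design notes

* Slow time is sampled once per frame (first chirp); the second chirp per
  frame is generated but unused — respiration bandwidth is far below the
  frame rate.
* Wrapped phases use the (−π, π] convention; `np.angle`'s −π output is
  folded to +π.
* The raw-capture reader uses a *declared* layout (headerless int16, I/Q
  pairs, channel-major per fast-time sample) that round-trips bit-exactly;
  an orientation self-check flags swapped I/Q pairs by the mirrored beat
  spectrum.
* Cross-correlation lag search is bounded to ±5 slow-time samples:
  inter-antenna geometric delays are sub-sample, and the bound prevents
  spurious locks on periodic signals.
* The denoiser benchmark scores each front-end by residual noise power
  1 − ρ², where ρ is the peak normalised cross-correlation (±3 samples)
  between the extracted waveform and the ground-truth band-limited
  differenced displacement phase. Its standard scene puts a strong static
  reflector in the *same* range bin as the chest (static torso parts /
  furniture — the classic DC-offset disturbance) plus a far reflector, at
  0 dB SNR. On this fixture raw is worst and overlay best; the
  single-delay canceller ranks worse than static-phasor removal because,
  with strictly stationary clutter, subtracting the time-mean is a
  near-optimal clutter estimate while the phase of a differenced phasor
  carries π-jumps wherever the breathing phase slope changes sign. On
  real, slowly drifting office clutter a high-pass canceller can
  outperform mean subtraction; that regime is outside the simulator's
  stationary-clutter model.

## Problem sizes

Unit and property tests run on records of 0.5–25 s. The end-to-end
classification experiments use 4 classes × 40 records × 25 s at
10 dB SNR with fivefold cross-validation over 5 seeds — the package's
desk-scale reference experiment (`respiradar demo` reproduces it from the
command line).

## Known limitations

* The simulator's clutter is point-like and stationary; drifting clutter,
  multipath and intermittent motion are not modelled.
* Breath counting assumes a normalised, band-limited waveform; applying
  the ±0.2 threshold to unnormalised data is unsupported.
* The classifier is validated on synthetic waveform images only; accuracy
  numbers characterise the simulation, not human subjects.
* Heart-rate extraction (0.8–2 Hz) is explicitly out of scope.
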