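# respiradar

Non-contact respiration monitoring and breathing-pattern classification
with simulated 77 GHz FMCW millimetre-wave radar.

Breathing moves the chest wall by a few millimetres at 0.1–0.5 Hz. An
FMCW radar mixing each transmitted chirp with its echo produces an
intermediate-frequency (IF) beat tone whose frequency encodes the target
range *R* and whose phase senses radial motion with sensitivity

    Δφ = (4π/λ)·Δd,          λ = c/fc ≈ 3.9 mm at fc = 77 GHz,

so sub-millimetre chest displacement is directly readable from the
slow-time phase of the thorax range bin. `respiradar` implements the
complete system for researchers in radar-based vital-sign sensing:

* a physically grounded **simulator** — chest displacement
  `xr(t) = Ar·(0.5 − sin^p(π·fr·t'))` repeated per breathing cycle (with
  breath-hold intervals for meningitic breathing), the dechirped IF
  signal model, static clutter, calibrated receiver noise and a
  four-channel receiver with unknown phase offsets;
* the **processing chain** — range FFT, thorax-bin selection, phase
  extraction/unwrapping/backward difference, multi-antenna denoising
  (signal overlay via cross-correlation-aligned coherent IQ summation,
  average phase cancellation, moving-target indication), elliptic
  0.1–0.5 Hz zero-phase bandpass, and spectral rate estimation;
* **breath counting** with a ±0.2 normalised-amplitude threshold and
  event-ordering rules (leading troughs discarded, repeated peaks
  collapsed, a trough closes each breath), plus rate estimates by peak
  counting, periodogram and autocorrelation;
* **pattern classification** of normal, slow/deep, quick and meningitic
  breathing from rendered 256 × 256 waveform images via HOG descriptors
  (9 orientation bins, 8 px cells, L2-normalised 2×2 blocks), PCA, and a
  one-vs-one soft-margin SVM (G-SVM) against a KNN baseline under
  stratified fivefold cross-validation.

See `docs/methods.md` for the model, parameter defaults and numerical
choices.

## Worked example

```python
import numpy as np
from respiradar import (RadarConfig, SceneConfig, pattern_presets,
                        synthesize_cube, extract_respiration, normalize,
                        count_breaths, respiration_rate)

radar = RadarConfig()                      # 77 GHz, 4 GHz sweep, 50 ms frames
pattern = pattern_presets("normal", seed=7)
scene = SceneConfig(target_range=0.8, snr_db=10.0,
                    clutter=((0.82, 0.5), (2.6, 1.0)), seed=7)

cube = synthesize_cube(pattern, scene, radar, duration=25.0)   # 500 frames
wave = extract_respiration(cube)           # signal-overlay denoising (default)
print(count_breaths(normalize(wave)).count)
for method in ("peaks", "spectral", "autocorrelation"):
    print(method, round(respiration_rate(wave, method), 2))
```

prints

```
6
peaks 14.43
spectral 16.89
autocorrelation 16.82
```

The drawn pattern breathes at 0.281 Hz (16.88 breaths/min): the spectral
and autocorrelation estimates land on it to within 0.1 bpm at 10 dB SNR,
while the counter closes 6 full breaths in the 25 s window (the ~7th
cycle is cut by the record boundary, so the peak-count rate reads low —
the known boundary bias of count-based rates on short records).

The same experiment end-to-end, including four-class classification, from
the shell:

```bash
respiradar demo --records 40 --snr-db 10 --seed 0 --out demo_run
```

prints the cross-validated accuracies of the HOG+SVM classifier and the
KNN baseline on 4 × 40 simulated 25 s records,

```json
{
  "g_svm_accuracy": 1.0,
  "knn_accuracy": 0.9625
}
```

and writes the full report (per-fold accuracies, 4 × 4 confusion matrix,
per-class accuracy) to `demo_run/report.json`. `respiradar simulate`,
`process`, `count`, `featurize` and `evaluate` run the individual stages
on serialized artifacts (HDF5 cubes, CSV waveforms, NPZ features, JSON
reports); raw int16 I/Q captures in a declared interleaved layout are
supported through `read_raw_bin`.

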