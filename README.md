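# cardiosynth

Synthetic paired ECG/PPG generation from a coupled ODE model, RR-interval
distribution metrics, and a contrastive-adversarial training harness for
reconstructing ECG waveforms from PPG signals.

## Why

The electrocardiogram (ECG) is the reference signal for cardiac
diagnosis, but it is awkward to record continuously; the
photoplethysmogram (PPG) from a wearable is easy to record and its
peak-to-peak intervals track the ECG's R-R intervals. Two problems follow
for anyone building PPG-to-ECG reconstruction models: paired ECG/PPG
corpora are scarce and noisy, and evaluating reconstructed rhythms needs
distribution-level metrics, not just sample-wise error. This package
addresses both for researchers in physiological signal processing:

1. **Simulation** — a five-state dynamical system generates paired
   ECG/PPG traces. A limit-cycle oscillator `(x, y)` sweeps one cardiac
   cycle per rotation; the ECG state integrates Gaussian-shaped pulls
   `-a_i * dθ_i * exp(-dθ_i² / 2b_i²)` at the P/Q/R/S/T reference angles;
   two further states low-pass the squared ECG into an optical pulse.
   Three rhythm presets (regular sinus rhythm, sinus arrhythmia, atrial
   fibrillation) and per-cycle frequency modulation
   `f_c = f̄ · mean(RR)/RR_c` impose any target R-R interval schedule —
   measurable directly from a real recording's PPG. White noise at 10% of
   each waveform parameter diversifies morphology.
2. **Metrics** — relative histogram intersection (rHI), relative RMSE,
   relative earth-mover's distance, KL divergence and the two-sample KS
   statistic on unit-width (1 ms) interval histograms, plus waveform
   RMSE, beat-wise heart-rate MAE, HRV summaries and the Fréchet distance
   between feature distributions.
3. **Reconstruction** — dual encoder/decoder generators (1-D attention
   U-Net or VQ-VAE) trained with NT-Xent contrastive alignment of the two
   latent spaces, smooth-L1 reconstruction terms, optional
   vector-quantization losses and time- plus frequency-domain patch
   discriminators, composited as `30·L_gen + 3·L_t + 1·L_f`. Inference
   runs only the PPG encoder and the ECG decoder. The networks run on the
   package's own numpy autodiff engine — no GPU framework required.

## Worked example

```python
import numpy as np
from cardiosynth import (rhythm_preset, simulate_pair, detect_peaks,
                         rr_from_peaks, unit_histograms, rhi, ks)

fs = 125.0
rng = np.random.default_rng(0)
schedule = np.round(rng.normal(800, 25, 75) * fs / 1000).astype(int)
pair = simulate_pair(rhythm_preset("RSR"), schedule, fs=fs,
                     seed=1, noise_frac=0.1)

detected = rr_from_peaks(detect_peaks(pair.ecg, fs))
target_ms = pair.rr_schedule / fs * 1000.0
ha, hb = unit_histograms(target_ms, detected.intervals)
print(f"rHI {rhi(ha, hb):.3f}  KS {ks(target_ms, detected.intervals):.3f}")
```

prints

```
rHI 1.000  KS 0.006
```

meaning the R-R intervals re-detected from the generated ECG reproduce
the driving schedule bin-for-bin on a 1 ms grid (rHI of 1 is an
identical histogram; the 0.6% CDF gap comes from the lead-in cycle before
the first detected peak). The
`examples/` directory holds one short script per capability —
simulation, RR-distribution emulation from PPG, preprocessing, and
training/reconstruction — each printing the numbers it computes.

A thin CLI mirrors the library:

```
cardiosynth simulate --rhythm afib --rr-mean 700 --rr-std 80 \
    --duration 60 --seed 3 --out afib.csv
cardiosynth rr --in afib.csv --channel ecg
cardiosynth demo-data --out-dir demo --n-per-rhythm 10
cardiosynth run --report report.json
```

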