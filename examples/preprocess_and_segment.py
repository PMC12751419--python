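"""The data-conditioning chain on one synthetic record.

Bandpass (0.4-45 Hz ECG / 0.3-8 Hz PPG), first-peak alignment, min-max
scaling to [-1, 1] and 512-sample windows with 50% overlap — the exact
shape the training harness consumes.
"""

import numpy as np

from cardiosynth import (align_first_peaks, bandpass, minmax_scale,
                         rhythm_preset, segment, simulate_pair)

fs = 125.0
pair = simulate_pair(rhythm_preset("RSR"), [100] * 40, fs=fs, seed=0,
                     noise_frac=0.1)

ecg = bandpass(pair.ecg, fs, 0.4, 45.0)
ppg = bandpass(pair.ppg, fs, 0.3, 8.0)
ecg, ppg = align_first_peaks(ecg, ppg, fs)
ecg, ppg = minmax_scale(ecg), minmax_scale(ppg)
ecg_segs = segment(ecg, window=512, overlap=0.5, fs=fs)
ppg_segs = segment(ppg, window=512, overlap=0.5, fs=fs)

print(f"record length after alignment: {len(ecg)} samples "
      f"({len(ecg) / fs:.1f} s)")
print(f"ECG range [{ecg.min():.2f}, {ecg.max():.2f}], "
      f"PPG range [{ppg.min():.2f}, {ppg.max():.2f}]")
print(f"{len(ecg_segs)} windows of {ecg_segs.window} samples at starts "
      f"{ecg_segs.starts[:4].tolist()}...")
print("\nEvery window is 512 samples (~4.1 s at 125 Hz); consecutive "
      "windows share half their samples.")
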