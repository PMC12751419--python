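"""Signal conditioning: bandpass filtering, resampling, alignment,
windowing and amplitude scaling.

The chain mirrors common practice for paired ECG/PPG work: 4th-order
Butterworth bandpass applied forward-backward (zero phase, so peak
positions are not shifted), polyphase anti-aliased resampling, first-peak
alignment of the two channels, fixed 512-sample windows with 50% overlap,
and per-record min-max scaling to [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .rr import detect_peaks

__all__ = [
    "SegmentSet", "bandpass", "resample", "align_first_peaks",
    "segment", "minmax_scale", "BAND_ECG", "BAND_PPG",
]

BAND_ECG = (0.4, 45.0)   # Hz
BAND_PPG = (0.3, 8.0)    # Hz


@dataclass
class SegmentSet:
    """Fixed-length windows cut from one record."""

    segments: np.ndarray      # (n, window)
    starts: np.ndarray        # (n,)
    fs: float

    def __post_init__(self):
        self.segments = np.asarray(self.segments, dtype=float)
        self.starts = np.asarray(self.starts, dtype=int)
        if self.segments.ndim != 2 and self.segments.size:
            raise ValueError("segments must be a 2-D array")

    def __len__(self):
        return len(self.segments)

    @property
    def window(self) -> int:
        return self.segments.shape[1] if self.segments.size else 0


def bandpass(signal: np.ndarray, fs: float, lo: float, hi: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass; same length as the input."""
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if hi >= fs / 2:
        raise ValueError(f"hi={hi} must be below the Nyquist rate {fs / 2}")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))


def resample(signal: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased polyphase rate conversion.

    Output length is ``round(N * fs_out / fs_in)``.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    signal = np.asarray(signal, dtype=float)
    if fs_in == fs_out:
        return signal.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    out = sps.resample_poly(signal, frac.numerator, frac.denominator)
    n_target = int(round(len(signal) * fs_out / fs_in))
    return out[:n_target]


def align_first_peaks(ecg: np.ndarray, ppg: np.ndarray,
                      fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Left-truncate the later-starting channel so both first peaks coincide.

    Avoids model-based ECG/PPG synchronization: the channel whose first
    detected peak occurs later is shifted back, then both are cut to equal
    length.
    """
    ecg = np.asarray(ecg, dtype=float)
    ppg = np.asarray(ppg, dtype=float)
    pe = detect_peaks(ecg, fs)
    pp = detect_peaks(ppg, fs)
    if len(pe) == 0 or len(pp) == 0:
        raise ValueError("no detectable peak in at least one channel")
    ie, ip = int(pe.indices[0]), int(pp.indices[0])
    if ie >= ip:
        ecg = ecg[ie - ip:]
    else:
        ppg = ppg[ip - ie:]
    n = min(len(ecg), len(ppg))
    return ecg[:n], ppg[:n]


def segment(signal: np.ndarray, window: int = 512,
            overlap: float = 0.5, fs: float = 125.0) -> SegmentSet:
    """Cut ``signal`` into windows of ``window`` samples with the given
    fractional overlap; an incomplete tail window is dropped."""
    if window <= 0:
        raise ValueError("window must be positive")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    signal = np.asarray(signal, dtype=float)
    hop = int(round(window * (1.0 - overlap)))
    starts = np.arange(0, len(signal) - window + 1, hop, dtype=int)
    segs = (np.stack([signal[s:s + window] for s in starts])
            if len(starts) else np.empty((0, window)))
    return SegmentSet(segments=segs, starts=starts, fs=fs)


def minmax_scale(signal: np.ndarray,
                 out_range: tuple[float, float] = (-1.0, 1.0)) -> np.ndarray:
    """Affine rescaling so min and max hit ``out_range`` exactly.

    A constant input has no defined scale; it maps to the range midpoint
    (all zeros for the default range) with a warning.
    """
    signal = np.asarray(signal, dtype=float)
    lo, hi = out_range
    smin, smax = signal.min(), signal.max()
    if smax == smin:
        warnings.warn("constant signal: min-max scaling maps it to the "
                      "range midpoint", stacklevel=2)
        return np.full_like(signal, (lo + hi) / 2.0)
    return lo + (signal - smin) * (hi - lo) / (smax - smin)
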