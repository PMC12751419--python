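"""Peak detection, RR-interval series, heart rate and HRV summaries.

The default R-peak detector is the distance + prominence local-maximum rule
(scipy's ``find_peaks`` with a 50-sample minimum separation); any callable
with the same signature can be plugged in instead.  A prominence floor of
0.3x the signal range keeps T waves of the synthetic presets from being
picked up as R peaks — a known failure mode of plain distance-based
detection on ECG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "PeakIndices", "RRSeries", "detect_peaks", "rr_from_peaks",
    "hr_from_rr", "hrv_summary", "rr_schedule_from_ppg",
]


@dataclass(frozen=True)
class PeakIndices:
    """Strictly increasing sample positions of detected peaks."""

    indices: np.ndarray
    fs: float

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.size > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "indices", idx)

    def __len__(self):
        return len(self.indices)


@dataclass(frozen=True)
class RRSeries:
    """Inter-beat intervals in milliseconds."""

    intervals: np.ndarray
    source_fs: float

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float)
        if np.any(iv <= 0):
            raise ValueError("all RR intervals must be positive")
        object.__setattr__(self, "intervals", iv)

    def __len__(self):
        return len(self.intervals)


Detector = Callable[[np.ndarray, float], PeakIndices]


def detect_peaks(signal: np.ndarray, fs: float, min_distance: int = 50,
                 min_prominence: float = 0.3) -> PeakIndices:
    """Local maxima separated by >= ``min_distance`` samples.

    ``min_prominence`` is a fraction of the signal's total range; a constant
    (or empty) signal yields an empty result rather than an error.
    """
    signal = np.asarray(signal, dtype=float)
    rng = float(signal.max() - signal.min()) if signal.size else 0.0
    if rng == 0.0:
        return PeakIndices(indices=np.array([], dtype=int), fs=fs)
    peaks, _ = find_peaks(signal, distance=min_distance,
                          prominence=min_prominence * rng)
    return PeakIndices(indices=peaks, fs=fs)


def rr_from_peaks(peaks: PeakIndices) -> RRSeries:
    """Successive peak spacings converted to milliseconds."""
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to form RR intervals")
    iv = np.diff(peaks.indices) / peaks.fs * 1000.0
    return RRSeries(intervals=iv, source_fs=peaks.fs)


def hr_from_rr(rr: RRSeries) -> np.ndarray:
    """Beat-wise heart rate, HR (BPM) = 60 / RR (seconds)."""
    iv = rr.intervals
    if np.any(iv == 0):
        raise ValueError("zero RR interval")
    return 60.0 / (iv / 1000.0)


def hrv_summary(rr: RRSeries) -> tuple[float, float]:
    """(mean, population STD) of the RR intervals, in milliseconds."""
    iv = rr.intervals
    if iv.size == 0:
        raise ValueError("empty RR series")
    return float(iv.mean()), float(iv.std())


def rr_schedule_from_ppg(ppg: np.ndarray, fs: float,
                         detector: Optional[Detector] = None) -> np.ndarray:
    """Per-cycle RR schedule (in samples) from PPG systolic peak spacings.

    The result can be fed directly to :func:`cardiosynth.ode.simulate_pair`
    to emulate the recording's inter-beat distribution.
    """
    detector = detector or detect_peaks
    peaks = detector(np.asarray(ppg, dtype=float), fs)
    if len(peaks) < 2:
        raise ValueError("PPG must contain at least 2 detectable peaks")
    return np.diff(peaks.indices)
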