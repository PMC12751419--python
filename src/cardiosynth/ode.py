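"""Coupled-ODE generation of paired synthetic ECG and PPG signals.

The ECG model is a limit-cycle oscillator: a point rotating on the unit
circle in the (x, y) plane drives a third state z whose derivative is a sum
of Gaussian-shaped pulls, one per cardiac wave (P, Q, R, S, T, plus extra
small waves for irregular rhythms).  Each wave *i* is parameterized by an
amplitude ``a_i``, an angular width ``b_i`` and a reference angle
``theta_i`` on the cycle; z(t) is the ECG trace.  Two further states couple
the ECG to an optical pulse signal: w integrates the squared ECG (a
rectified proxy for ventricular contraction) and v — the PPG trace — is a
low-passed, decaying response to w.

Heart-rate variability is imposed through the angular velocity: given a
schedule of RR intervals (one per cycle, in samples), the rotation frequency
of cycle *c* is ``fbar * mean(RR) / RR_c``, so each inter-beat gap spans
exactly ``RR_c`` output samples.  The frequency is updated when the phase
crosses the R-peak angle (theta = 0), which pins successive R-peak spacings
to the schedule entries.

Morphological diversity is added by perturbing (a, b, theta) with white
noise whose standard deviation is a fraction (default 10%) of each
parameter's magnitude, drawn once per generated pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "WaveformParams", "CouplingConstants", "RhythmPreset", "SignalPair",
    "U0", "derivatives", "frequency_for_cycle", "perturb_params",
    "rhythm_preset", "simulate_pair", "RHYTHMS",
]

#: Initial state [x, y, z, v, w].
U0 = np.array([1.0 / np.sqrt(2.0), 1.0 / np.sqrt(2.0), 0.2, 0.005, 0.0])


@dataclass(frozen=True)
class WaveformParams:
    """Amplitude / width / reference-angle vectors of the cardiac waves."""

    a: np.ndarray
    b: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        if not (len(self.a) == len(self.b) == len(self.theta)):
            raise ValueError("a, b, theta must have equal length")
        if len(self.a) < 5:
            raise ValueError("at least 5 waves (P, Q, R, S, T) are required")
        if np.any(self.b <= 0):
            raise ValueError("all widths b must be strictly positive")
        if np.any(np.diff(self.theta) <= 0):
            raise ValueError("theta must be strictly increasing")

    @property
    def n_waves(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class CouplingConstants:
    """Baseline-wander and ECG-to-PPG coupling constants (per ODE time unit)."""

    A: float = 0.01      # baseline-wander amplitude
    f0: float = 0.25     # baseline-wander frequency
    B0: float = 0.5      # PPG decay rate
    B1: float = 0.5      # w -> v coupling
    B2: float = 1.25     # intermediary decay rate
    fbar: float = 0.1    # base cycle frequency (60 BPM when RRbar == fs)

    def __post_init__(self):
        if self.A < 0:
            raise ValueError("A must be >= 0")
        for name in ("f0", "B0", "B1", "B2", "fbar"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class RhythmPreset:
    name: str
    params: WaveformParams
    constants: CouplingConstants = field(default_factory=CouplingConstants)


@dataclass
class SignalPair:
    """An aligned synthetic ECG/PPG pair and the schedule that produced it."""

    ecg: np.ndarray
    ppg: np.ndarray
    fs: float
    rr_schedule: np.ndarray
    rhythm: str
    seed: int

    def __post_init__(self):
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        if len(self.ecg) != len(self.ppg):
            raise ValueError("ecg and ppg must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.rr_schedule = np.asarray(self.rr_schedule, dtype=int)

    @property
    def duration(self) -> float:
        return len(self.ecg) / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.ecg)) / self.fs


_PRESETS = {
    "RSR": WaveformParams(
        a=[1.2, -5.0, 30.0, -7.5, 0.75],
        b=[0.25, 0.1, 0.1, 0.1, 0.4],
        theta=[-np.pi / 3, -np.pi / 12, 0.0, np.pi / 12, np.pi / 2],
    ),
    "SA": WaveformParams(
        a=[1.0, 2.0, 3.0, 3.0, 2.5, -1.0, 0.5],
        b=[0.2, 0.15, 0.15, 0.2, 0.15, 0.2, 0.4],
        theta=[-np.pi / 1.5, -np.pi / 2.0, -np.pi / 6.5, -np.pi / 12.0,
               0.0, np.pi / 12.0, np.pi / 1.5],
    ),
    "AFIB": WaveformParams(
        a=[-1.0, 0.5, 1.0, -2.0, 25.0, -10.0, 2.0, -2.0, 0.5, 0.5, 0.5],
        b=[0.1, 0.15, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.2, 0.2, 0.2],
        theta=[-np.pi / 2.0, -np.pi / 3.0, -np.pi / 5.0, -np.pi / 12.0, 0.0,
               np.pi / 12.0, np.pi / 6.0, np.pi / 5.0, np.pi / 2.5,
               np.pi / 2.0, np.pi / 1.5],
    ),
}

RHYTHMS = ("RSR", "SA", "AFib")


def rhythm_preset(name: str) -> RhythmPreset:
    """Return the waveform parameter preset for one of the three rhythms.

    ``RSR`` (regular sinus rhythm) uses the five canonical P/Q/R/S/T waves;
    ``SA`` (sinus arrhythmia) adds two waves to mimic erratic P waves; and
    ``AFib`` (atrial fibrillation) adds six, replacing coherent P/T activity
    with low-amplitude fibrillatory undulation.
    """
    key = name.strip().upper().replace(".", "")
    if key not in _PRESETS:
        raise ValueError(
            f"unknown rhythm {name!r}; valid names: RSR, SA, AFib")
    canonical = {"RSR": "RSR", "SA": "SA", "AFIB": "AFib"}[key]
    return RhythmPreset(name=canonical, params=_PRESETS[key])


def _wrap_angle(d: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    d = np.mod(d + np.pi, 2.0 * np.pi) - np.pi
    return np.where(d == -np.pi, np.pi, d)


def derivatives(u: np.ndarray, t: float, params: WaveformParams,
                constants: CouplingConstants, f: float) -> np.ndarray:
    """Time derivatives [dx, dy, dz, dv, dw] of the coupled system.

    dx/dt = alpha*x - omega*y,  dy/dt = alpha*y + omega*x  (limit cycle),
    dz/dt = -sum_i a_i * dtheta_i * exp(-dtheta_i^2 / 2 b_i^2) - (z - z0),
    dv/dt = -B0*v + B1*w,       dw/dt = z^2 - B2*w,
    with alpha = 1 - sqrt(x^2+y^2), theta = atan2(y, x), omega = 2*pi*f and
    baseline z0 = A*sin(2*pi*f0*t).
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("non-finite state: integration blew up")
    x, y, z, v, w = u
    alpha = 1.0 - np.hypot(x, y)
    theta = np.arctan2(y, x)
    omega = 2.0 * np.pi * f
    z0 = constants.A * np.sin(2.0 * np.pi * constants.f0 * t)
    dtheta = _wrap_angle(theta - params.theta)
    dz = -np.sum(params.a * dtheta * np.exp(-dtheta ** 2 / (2.0 * params.b ** 2)))
    dz -= (z - z0)
    return np.array([
        alpha * x - omega * y,
        alpha * y + omega * x,
        dz,
        -constants.B0 * v + constants.B1 * w,
        z * z - constants.B2 * w,
    ])


def frequency_for_cycle(fbar: float, rr_mean: float, rr_c: float) -> float:
    """Cycle frequency f = fbar * mean(RR) / RR_c."""
    if fbar <= 0 or rr_mean <= 0:
        raise ValueError("fbar and rr_mean must be positive")
    if rr_c <= 0:
        raise ValueError("rr_c must be positive")
    return fbar * rr_mean / rr_c


def perturb_params(params: WaveformParams, frac: float,
                   rng: np.random.Generator) -> WaveformParams:
    """Add zero-mean white noise with STD = ``frac * |value|`` per element.

    Widths are floored at a small positive fraction of their original value
    so the Gaussian pulls stay well defined; if the perturbed reference
    angles lose monotonicity the three vectors are re-sorted jointly by
    angle (the wave set is unchanged, only its ordering).
    """
    if frac < 0:
        raise ValueError("frac must be >= 0")
    if frac == 0:
        return params
    a = params.a + rng.normal(0.0, frac * np.abs(params.a))
    b = params.b + rng.normal(0.0, frac * np.abs(params.b))
    theta = params.theta + rng.normal(0.0, frac * np.abs(params.theta))
    b = np.maximum(b, 0.05 * params.b)
    order = np.argsort(theta, kind="stable")
    return WaveformParams(a=a[order], b=b[order], theta=theta[order])


def simulate_pair(preset: RhythmPreset, rr_schedule: Sequence[int],
                  fs: float = 125.0, seed: int = 0,
                  noise_frac: float = 0.0) -> SignalPair:
    """Integrate the coupled system and sample paired ECG/PPG traces.

    One classical 4th-order Runge–Kutta step is taken per output sample,
    with a step of ``1 / (fbar * mean(rr_schedule))`` ODE time units, so a
    cycle at the base frequency spans exactly the mean RR in samples.  The
    rotation frequency is piecewise-constant per cycle and updated when the
    phase crosses the R-peak angle, pinning R-peak spacings to the schedule.
    Fixed-step integration keeps the output bit-reproducible for a given
    (preset, schedule, fs, seed, noise_frac).
    """
    rr = np.asarray(rr_schedule, dtype=float)
    if rr.size == 0:
        raise ValueError("rr_schedule must be non-empty")
    if np.any(rr <= 0):
        raise ValueError("all rr_schedule entries must be positive")

    rng = np.random.default_rng(seed)
    params = perturb_params(preset.params, noise_frac, rng)
    consts = preset.constants
    rr_mean = rr.mean()
    dt = 1.0 / (consts.fbar * rr_mean)

    n_samples = int(round(rr.sum()))
    u = U0.copy()
    t = 0.0
    cycle = 0
    f = frequency_for_cycle(consts.fbar, rr_mean, rr[0])
    ecg = np.empty(n_samples)
    ppg = np.empty(n_samples)
    theta_prev = np.arctan2(u[1], u[0])

    for i in range(n_samples):
        k1 = derivatives(u, t, params, consts, f)
        k2 = derivatives(u + 0.5 * dt * k1, t + 0.5 * dt, params, consts, f)
        k3 = derivatives(u + 0.5 * dt * k2, t + 0.5 * dt, params, consts, f)
        k4 = derivatives(u + dt * k3, t + dt, params, consts, f)
        u = u + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t += dt
        ecg[i] = u[2]
        ppg[i] = u[3]
        theta = np.arctan2(u[1], u[0])
        # upward crossing of theta = 0: the R peak -> next cycle's frequency
        if theta_prev < 0.0 <= theta and theta - theta_prev < np.pi:
            cycle += 1
            f = frequency_for_cycle(consts.fbar, rr_mean,
                                    rr[min(cycle, rr.size - 1)])
        theta_prev = theta

    if not (np.all(np.isfinite(ecg)) and np.all(np.isfinite(ppg))):
        raise FloatingPointError("integration diverged")
    return SignalPair(ecg=ecg, ppg=ppg, fs=fs, rr_schedule=rr.astype(int),
                      rhythm=preset.name, seed=seed)
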