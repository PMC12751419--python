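"""Quantitative comparison measures.

Two families:

* RR-distribution metrics — relative histogram intersection (rHI),
  relative RMSE (rRMSE), relative earth-mover's distance (rEMD), KL
  divergence and the two-sample Kolmogorov–Smirnov statistic — computed on
  unit-width (1 ms) histograms over the union support of the two interval
  samples, so bin-size choices cannot tilt the comparison;
* waveform / reconstruction metrics — signal RMSE, mean absolute heart-rate
  error (MAE_HR), HRV summaries, and the Fréchet distance (FD) between
  Gaussian fits of per-segment feature distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats

from .rr import RRSeries, hr_from_rr, hrv_summary

__all__ = [
    "UnitHistogram", "FeatureCloud", "MetricReport", "unit_histograms",
    "rhi", "rrmse", "remd", "kl", "ks", "rmse", "mae_hr",
    "frechet_distance", "default_feature_extractor", "rr_metric_report",
]

ArrayLike = Union[np.ndarray, list, tuple, RRSeries]


def _values(x: ArrayLike) -> np.ndarray:
    if isinstance(x, RRSeries):
        return x.intervals
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class UnitHistogram:
    """Counts over contiguous unit-width bins; ``bin_edges[i]`` is the left
    edge of bin *i* (``len(bin_edges) == len(counts) + 1``)."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges)
        counts = np.asarray(self.counts, dtype=float)
        if len(edges) != len(counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if np.any(np.diff(edges) != 1):
            raise ValueError("bins must be contiguous with unit width")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def unit_histograms(a: ArrayLike, b: ArrayLike) -> tuple[UnitHistogram, UnitHistogram]:
    """Histogram two samples on a shared integer-edged unit-bin grid
    spanning the union of their supports."""
    av, bv = _values(a), _values(b)
    if av.size == 0 or bv.size == 0:
        raise ValueError("empty sample")
    lo = int(np.floor(min(av.min(), bv.min())))
    hi = int(np.floor(max(av.max(), bv.max()))) + 1
    edges = np.arange(lo, hi + 1)
    ca, _ = np.histogram(av, bins=edges)
    cb, _ = np.histogram(bv, bins=edges)
    return UnitHistogram(edges, ca), UnitHistogram(edges, cb)


def _check_grid(ha: UnitHistogram, hb: UnitHistogram):
    if not np.array_equal(ha.bin_edges, hb.bin_edges):
        raise ValueError("histograms must share a bin grid")
    if ha.total == 0 or hb.total == 0:
        raise ValueError("empty histogram")


def rhi(ha: UnitHistogram, hb: UnitHistogram) -> float:
    """Relative histogram intersection: sum of per-bin minima over the
    smaller total count.  1 for identical histograms, 0 for disjoint."""
    _check_grid(ha, hb)
    inter = np.minimum(ha.counts, hb.counts).sum()
    return float(inter / min(ha.total, hb.total))


def rrmse(rr_a: ArrayLike, rr_b: ArrayLike) -> float:
    """RMSE between the two interval samples divided by the reference mean.

    Values are paired after sorting (monotone coupling); when the counts
    differ, B is quantile-interpolated onto A's N points.
    """
    av = np.sort(_values(rr_a))
    bv = np.sort(_values(rr_b))
    if av.size == 0 or bv.size == 0:
        raise ValueError("empty RR series")
    if av.size != bv.size:
        q = np.linspace(0.0, 1.0, av.size)
        bv = np.quantile(bv, q)
    err = np.sqrt(np.mean((av - bv) ** 2))
    return float(err / av.mean())


def remd(ha: UnitHistogram, hb: UnitHistogram) -> float:
    """Relative earth-mover's distance on a shared unit-bin grid.

    B's counts are rescaled to A's total, the EMD is the L1 distance
    between cumulative counts, and the normalizer is the maximum possible
    EMD: (total count of A) x (largest inter-bin distance).
    """
    _check_grid(ha, hb)
    nbins = len(ha.counts)
    cb = hb.counts * (ha.total / hb.total)
    fa = np.cumsum(ha.counts)
    fb = np.cumsum(cb)
    emd = float(np.abs(fa - fb).sum())  # binwidth = 1
    if nbins == 1:
        # after renormalization both histograms place all mass in the one
        # bin, so they coincide and the distance is zero
        return 0.0
    return emd / (ha.total * (nbins - 1))


def kl(ha: UnitHistogram, hb: UnitHistogram, eps: float = 1e-9) -> float:
    """KL(P || Q), natural log, after additive-eps smoothing of both
    normalized histograms (so empty bins do not produce infinities)."""
    _check_grid(ha, hb)
    p = ha.counts / ha.total + eps
    q = hb.counts / hb.total + eps
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def ks(rr_a: ArrayLike, rr_b: ArrayLike) -> float:
    """Two-sample Kolmogorov–Smirnov statistic: the largest gap between the
    empirical CDFs."""
    av, bv = _values(rr_a), _values(rr_b)
    if av.size == 0 or bv.size == 0:
        raise ValueError("empty sample")
    return float(stats.ks_2samp(av, bv, method="asymp").statistic)


def rmse(sig_g: np.ndarray, sig_r: np.ndarray) -> float:
    """Root-mean-square error between two equal-length signals."""
    g = np.asarray(sig_g, dtype=float)
    r = np.asarray(sig_r, dtype=float)
    if g.shape != r.shape:
        raise ValueError(f"length mismatch: {g.shape} vs {r.shape}")
    return float(np.sqrt(np.mean((g - r) ** 2)))


def mae_hr(rr_g: ArrayLike, rr_r: ArrayLike) -> float:
    """Mean absolute beat-wise heart-rate error in BPM; the two series are
    truncated to their common beat count."""
    gv, rv = _values(rr_g), _values(rr_r)
    n = min(gv.size, rv.size)
    if n == 0:
        raise ValueError("empty RR series")
    hr_g = 60.0 / (gv[:n] / 1000.0)
    hr_r = 60.0 / (rv[:n] / 1000.0)
    return float(np.mean(np.abs(hr_g - hr_r)))


# --------------------------------------------------------------------------
# Fréchet distance in feature space
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureCloud:
    """Gaussian summary (mean, covariance) of per-segment feature vectors."""

    mu: np.ndarray
    sigma: np.ndarray
    extractor: str = "unspecified"

    @classmethod
    def from_features(cls, features: np.ndarray,
                      extractor: str = "unspecified") -> "FeatureCloud":
        f = np.asarray(features, dtype=float)
        if f.ndim != 2 or f.shape[0] < 2:
            raise ValueError("need an (n >= 2) x d feature matrix")
        mu = f.mean(axis=0)
        sigma = np.cov(f, rowvar=False)
        sigma = np.atleast_2d(sigma)
        return cls(mu=mu, sigma=sigma, extractor=extractor)


def _psd_sqrt(m: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition, negative
    eigenvalues clipped at zero."""
    vals, vecs = np.linalg.eigh((m + m.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T

def frechet_distance(real: FeatureCloud, gen: FeatureCloud) -> float:
    """||mu_r - mu_g||^2 + Tr(S_r + S_g - 2 (S_r S_g)^{1/2}).

    The cross term is evaluated in its symmetrized form
    ``sqrt(sqrt(S_r) S_g sqrt(S_r))`` so only PSD square roots are needed.
    """
    if real.mu.shape != gen.mu.shape:
        raise ValueError("feature dimension mismatch")
    diff = real.mu - gen.mu
    s = _psd_sqrt(real.sigma)
    inner = _psd_sqrt(s @ gen.sigma @ s)
    fd = float(diff @ diff + np.trace(real.sigma) + np.trace(gen.sigma)
               - 2.0 * np.trace(inner))
    return max(fd, 0.0)


def default_feature_extractor(segments, kind: str = "stft") -> FeatureCloud:
    """Deterministic per-segment features for the Fréchet distance.

    ``stft`` (default): flattened log-magnitude spectrogram frames;
    ``raw``: the segment samples themselves.  The extractor identity is
    recorded on the returned cloud.
    """
    from .framework import stft_spectrogram  # local import avoids a cycle

    segs = segments.segments if hasattr(segments, "segments") else np.asarray(segments)
    if len(segs) < 2:
        raise ValueError("need at least 2 segments")
    if kind == "raw":
        feats = np.asarray(segs, dtype=float)
    elif kind == "stft":
        feats = np.stack([
            np.log(stft_spectrogram(s) + 1e-8).ravel() for s in segs])
    else:
        raise ValueError(f"unknown extractor kind {kind!r}")
    return FeatureCloud.from_features(feats, extractor=kind)


@dataclass
class MetricReport:
    """One comparison's full metric bundle."""

    rhi: float
    rrmse: float
    remd: float
    kl: float
    ks: float
    rmse: Optional[float] = None
    mae_hr: Optional[float] = None
    hrv_mean: Optional[float] = None
    hrv_std: Optional[float] = None
    fd: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("rhi", "rrmse", "remd", "kl", "ks", "rmse", "mae_hr",
              "hrv_mean", "hrv_std", "fd")}
        d["metadata"] = dict(self.metadata)
        return d


def rr_metric_report(rr_ref: ArrayLike, rr_other: ArrayLike,
                     **extra) -> MetricReport:
    """The five RR-distribution metrics for a reference/other interval pair,
    plus HRV summaries of the reference."""
    ha, hb = unit_histograms(rr_ref, rr_other)
    ref = rr_ref if isinstance(rr_ref, RRSeries) else RRSeries(
        intervals=_values(rr_ref), source_fs=0.0)
    mean, std = hrv_summary(ref)
    return MetricReport(
        rhi=rhi(ha, hb), rrmse=rrmse(rr_ref, rr_other), remd=remd(ha, hb),
        kl=kl(ha, hb), ks=ks(rr_ref, rr_other),
        mae_hr=mae_hr(rr_ref, rr_other),
        hrv_mean=mean, hrv_std=std, metadata=dict(extra))
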