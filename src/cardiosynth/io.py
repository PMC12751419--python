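"""Record I/O, the packaged demo-dataset generator, and the end-to-end
simulate -> preprocess -> train -> reconstruct -> evaluate pipeline.

Formats: CSV (columns ``t_sec, ecg, ppg``), HDF5 (datasets ``/ecg``,
``/ppg`` with ``fs``/``rhythm``/``seed``/``rr_schedule`` attributes) and —
when the optional ``wfdb`` package is installed — PhysioNet WFDB records.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as mx
from . import preprocess as pp
from .framework import TrainConfig, TrainResult, reconstruct, train
from .ode import RHYTHMS, SignalPair, rhythm_preset, simulate_pair
from .rr import detect_peaks, rr_from_peaks, rr_schedule_from_ppg

__all__ = [
    "RecordBundle", "load_record", "write_record", "make_demo_dataset",
    "demo_pairs", "run_pipeline", "rr_table_comparison",
]


@dataclass
class RecordBundle:
    """One loaded ECG/PPG record plus provenance metadata."""

    record_id: str
    ecg: np.ndarray
    ppg: np.ndarray
    fs: float
    provenance: str = "synthetic"            # synthetic | wfdb | csv | hdf5
    sex: Optional[str] = None
    age: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def write_record(path: str, pair: SignalPair, fmt: Optional[str] = None) -> None:
    """Write a signal pair as CSV (t_sec, ecg, ppg) or HDF5."""
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix == ".csv" else "hdf5")
    if fmt == "csv":
        pd.DataFrame({"t_sec": pair.t, "ecg": pair.ecg, "ppg": pair.ppg}
                     ).to_csv(path, index=False, float_format="%.9g")
    elif fmt == "hdf5":
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("ecg", data=pair.ecg)
            f.create_dataset("ppg", data=pair.ppg)
            f.attrs["fs"] = pair.fs
            f.attrs["rhythm"] = pair.rhythm
            f.attrs["seed"] = pair.seed
            f.attrs["rr_schedule"] = pair.rr_schedule
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def load_record(path: str, fmt: Optional[str] = None,
                fs: Optional[float] = None) -> RecordBundle:
    """Load an ECG/PPG record from CSV, HDF5 or (optionally) WFDB.

    CSV needs ``ecg`` and ``ppg`` columns and either a ``t_sec`` column or
    an explicit ``fs``.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".h5": "hdf5", ".hdf5": "hdf5",
               ".hea": "wfdb", ".dat": "wfdb"}.get(path.suffix, None)
    if fmt == "csv":
        df = pd.read_csv(path)
        missing = {"ecg", "ppg"} - set(df.columns)
        if missing:
            raise ValueError(
                f"missing channel(s) {sorted(missing)}; available columns: "
                f"{list(df.columns)}")
        if fs is None:
            if "t_sec" not in df.columns:
                raise ValueError("CSV without t_sec column requires fs")
            fs = 1.0 / float(np.median(np.diff(df["t_sec"].to_numpy())))
        return RecordBundle(record_id=path.stem, ecg=df["ecg"].to_numpy(),
                            ppg=df["ppg"].to_numpy(), fs=fs, provenance="csv")
    if fmt == "hdf5":
        import h5py
        with h5py.File(path, "r") as f:
            for key in ("ecg", "ppg"):
                if key not in f:
                    raise ValueError(f"missing channel {key!r}; available: "
                                     f"{list(f.keys())}")
            bundle = RecordBundle(
                record_id=path.stem, ecg=f["ecg"][()], ppg=f["ppg"][()],
                fs=float(f.attrs["fs"]), provenance="hdf5",
                extra={k: f.attrs[k] for k in f.attrs if k != "fs"})
        return bundle
    if fmt == "wfdb":
        try:
            import wfdb
        except ImportError as err:
            raise ImportError(
                "reading WFDB records requires the optional 'wfdb' package"
            ) from err
        rec = wfdb.rdrecord(str(path.with_suffix("")))
        names = [s.upper() for s in rec.sig_name]
        def pick(cands):
            for c in cands:
                for i, nm in enumerate(names):
                    if c in nm:
                        return rec.p_signal[:, i]
            raise ValueError(f"no channel matching {cands} in {rec.sig_name}")
        return RecordBundle(record_id=path.stem,
                            ecg=pick(("II", "ECG", "V")),
                            ppg=pick(("PLETH", "PPG")),
                            fs=float(rec.fs), provenance="wfdb")
    raise ValueError(f"unsupported format {fmt!r} for {path}")


# --------------------------------------------------------------------------
# Demo dataset
# --------------------------------------------------------------------------

def _draw_schedule(rng, rr_mean_ms, rr_std_ms, duration_s, fs):
    n_cycles = max(int(np.ceil(duration_s * 1000.0 / rr_mean_ms)), 2)
    ms = rng.normal(rr_mean_ms, rr_std_ms, size=n_cycles)
    ms = np.clip(ms, 300.0, 2000.0)
    return np.maximum(np.round(ms * fs / 1000.0).astype(int), 1)


def demo_pairs(n_per_rhythm: int = 10,
               rr_mean_range: tuple = (600.0, 1000.0),
               rr_std_range: tuple = (10.0, 50.0),
               duration_s: float = 60.0, fs: float = 125.0,
               noise_frac: float = 0.1, seed: int = 0,
               rhythms: Sequence[str] = RHYTHMS) -> list[SignalPair]:
    """Generate a small in-memory corpus: ``n_per_rhythm`` pairs for each
    rhythm, with per-record RR mean/STD drawn uniformly from the given
    ranges (ms) and waveform parameters perturbed by ``noise_frac``."""
    if n_per_rhythm < 1:
        raise ValueError("n_per_rhythm must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = []
    for rhythm in rhythms:
        preset = rhythm_preset(rhythm)
        for i in range(n_per_rhythm):
            rr_mean = rng.uniform(*rr_mean_range)
            rr_std = rng.uniform(*rr_std_range)
            schedule = _draw_schedule(rng, rr_mean, rr_std, duration_s, fs)
            pair_seed = int(rng.integers(0, 2 ** 31 - 1))
            pairs.append(simulate_pair(preset, schedule, fs=fs,
                                       seed=pair_seed, noise_frac=noise_frac))
    return pairs


def make_demo_dataset(out_dir: str, n_per_rhythm: int = 10,
                      rr_mean_range: tuple = (600.0, 1000.0),
                      rr_std_range: tuple = (10.0, 50.0),
                      duration_s: float = 60.0, fs: float = 125.0,
                      noise_frac: float = 0.1, seed: int = 0) -> dict:
    """Write a demo corpus to ``out_dir`` (HDF5 pairs + JSON manifest).

    The manifest records ids, rhythms, seeds and per-record RR statistics;
    it fully reconstructs the dataset under the same top-level seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs = demo_pairs(n_per_rhythm, rr_mean_range, rr_std_range,
                       duration_s, fs, noise_frac, seed)
    entries = []
    for i, pair in enumerate(pairs):
        rid = f"{pair.rhythm.lower()}_{i % n_per_rhythm:03d}"
        fname = f"{rid}.h5"
        write_record(out / fname, pair)
        rr_ms = pair.rr_schedule / fs * 1000.0
        entries.append({
            "id": rid, "file": fname, "rhythm": pair.rhythm,
            "seed": pair.seed, "fs": fs,
            "rr_mean_ms": round(float(rr_ms.mean()), 6),
            "rr_std_ms": round(float(rr_ms.std()), 6),
            "n_cycles": int(len(pair.rr_schedule)),
        })
    manifest = {"seed": seed, "n_per_rhythm": n_per_rhythm,
                "rr_mean_range_ms": list(rr_mean_range),
                "rr_std_range_ms": list(rr_std_range),
                "duration_s": duration_s, "fs": fs,
                "noise_frac": noise_frac, "records": entries}
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return manifest


# --------------------------------------------------------------------------
# End-to-end pipeline
# --------------------------------------------------------------------------

_PIPELINE_DEFAULTS = {
    "dataset": {"kind": "demo", "n_per_rhythm": 4, "duration_s": 30.0,
                "fs": 125.0, "noise_frac": 0.1, "seed": 0,
                "rr_mean_range": [600.0, 1000.0],
                "rr_std_range": [10.0, 40.0]},
    "split": {"test_frac": 0.15, "seed": 0},
    "train": {"epochs": 10, "batch_size": 32, "lr": 2e-4, "seed": 0,
              "generator": {}, "weights": {}},
    "evaluate": {"feature_extractor": "stft"},
    "window": 512,
    "overlap": 0.5,
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = dict(defaults)
    for k, v in (user or {}).items():
        if k not in defaults:
            raise ValueError(f"unknown config field {path + k!r}")
        if isinstance(defaults[k], dict) and not k in ("generator", "weights"):
            out[k] = _merge(defaults[k], v, path + k + ".")
        else:
            out[k] = v
    return out


def _prep_pair(ecg, ppg, fs, window, overlap):
    ecg_f = pp.bandpass(ecg, fs, *pp.BAND_ECG)
    ppg_f = pp.bandpass(ppg, fs, *pp.BAND_PPG)
    ecg_a, ppg_a = pp.align_first_peaks(ecg_f, ppg_f, fs)
    ecg_s = pp.minmax_scale(ecg_a)
    ppg_s = pp.minmax_scale(ppg_a)
    return (pp.segment(ecg_s, window, overlap, fs),
            pp.segment(ppg_s, window, overlap, fs))


def run_pipeline(config: Optional[dict] = None,
                 out_path: Optional[str] = None) -> dict:
    """Simulate (or load) -> preprocess -> train -> reconstruct -> evaluate.

    Returns a JSON-serializable report: per-test-record metric bundles and
    their averages.  A held-out fraction of records never enters training.
    """
    from .losses import LossWeights
    from .framework import GeneratorSpec

    cfg = _merge(_PIPELINE_DEFAULTS, config or {})
    window, overlap = cfg["window"], cfg["overlap"]

    ds = cfg["dataset"]
    if ds["kind"] == "demo":
        pairs = demo_pairs(
            n_per_rhythm=ds["n_per_rhythm"], duration_s=ds["duration_s"],
            fs=ds["fs"], noise_frac=ds["noise_frac"], seed=ds["seed"],
            rr_mean_range=tuple(ds["rr_mean_range"]),
            rr_std_range=tuple(ds["rr_std_range"]))
        records = [RecordBundle(record_id=f"{p.rhythm.lower()}_{i:03d}",
                                ecg=p.ecg, ppg=p.ppg, fs=p.fs)
                   for i, p in enumerate(pairs)]
    elif ds["kind"] == "files":
        records = [load_record(p) for p in ds["paths"]]
    else:
        raise ValueError("dataset.kind must be 'demo' or 'files'")

    split_rng = np.random.default_rng(cfg["split"]["seed"])
    n_test = max(int(round(cfg["split"]["test_frac"] * len(records))), 1)
    test_idx = set(split_rng.choice(len(records), size=n_test, replace=False)
                   .tolist())
    train_recs = [r for i, r in enumerate(records) if i not in test_idx]
    test_recs = [r for i, r in enumerate(records) if i in test_idx]

    tr = cfg["train"]
    tconf = TrainConfig(epochs=tr["epochs"], batch_size=tr["batch_size"],
                        window=window, lr=tr["lr"], seed=tr["seed"],
                        weights=LossWeights(**tr["weights"]),
                        generator=GeneratorSpec(**tr["generator"]))
    ecg_segs, ppg_segs = [], []
    for rec in train_recs:
        es, ps = _prep_pair(rec.ecg, rec.ppg, rec.fs, window, overlap)
        ecg_segs.append(es.segments)
        ppg_segs.append(ps.segments)
    result: TrainResult = train(np.concatenate(ecg_segs),
                                np.concatenate(ppg_segs), tconf)

    reports = {}
    for rec in test_recs:
        es, ps = _prep_pair(rec.ecg, rec.ppg, rec.fs, window, overlap=0.0)
        if len(es) == 0:
            continue
        pred = reconstruct(ps.segments, result.checkpoint)
        true_ecg = es.segments.ravel()
        pred_ecg = pred.ravel()
        rep = _evaluate_reconstruction(true_ecg, pred_ecg, es.segments, pred,
                                       rec.fs, cfg["evaluate"]["feature_extractor"])
        reports[rec.record_id] = rep.to_dict()

    keys = ("rhi", "rrmse", "remd", "kl", "ks", "rmse", "mae_hr", "fd")
    avg = {k: float(np.mean([r[k] for r in reports.values()
                             if r[k] is not None])) for k in keys}
    report = {
        "config": cfg,
        "train_records": [r.record_id for r in train_recs],
        "test_records": [r.record_id for r in test_recs],
        "history": result.history,
        "per_record": reports,
        "average": avg,
    }
    if out_path is not None:
        with open(out_path, "w") as f:
            json.dump(report, f, indent=1, default=float)
    return report


def _evaluate_reconstruction(true_ecg, pred_ecg, true_segs, pred_segs, fs,
                             extractor="stft") -> mx.MetricReport:
    """Full metric bundle for a reconstructed ECG against its ground truth."""
    rr_true = rr_from_peaks(detect_peaks(true_ecg, fs))
    rr_pred = rr_from_peaks(detect_peaks(pred_ecg, fs))
    rep = mx.rr_metric_report(rr_true, rr_pred)
    rep.rmse = mx.rmse(true_ecg, pred_ecg)
    if len(true_segs) >= 2 and len(pred_segs) >= 2:
        rep.fd = mx.frechet_distance(
            mx.default_feature_extractor(true_segs, extractor),
            mx.default_feature_extractor(pred_segs, extractor))
    rep.metadata["feature_extractor"] = extractor
    return rep


# --------------------------------------------------------------------------
# RR-distribution emulation of real records
# --------------------------------------------------------------------------

def rr_table_comparison(record_paths: Sequence[str], rhythm: str = "RSR",
                        noise_frac: float = 0.1, seed: int = 0,
                        fs_target: float = 125.0) -> dict:
    """Per-record RR-distribution agreement between each real recording and
    a synthetic pair driven by the recording's own PPG peak-to-peak
    schedule; returns per-record metric bundles and their averages.

    This is the evaluation used to validate that simulated RR
    distributions track real ones (requires real paired recordings, e.g.
    PhysioNet BIDMC, downloaded separately).
    """
    preset = rhythm_preset(rhythm)
    per_record, rows = {}, []
    for i, path in enumerate(record_paths):
        rec = load_record(path)
        ecg, ppg, fs = rec.ecg, rec.ppg, rec.fs
        if fs != fs_target:
            ecg = pp.resample(ecg, fs, fs_target)
            ppg = pp.resample(ppg, fs, fs_target)
            fs = fs_target
        ecg = pp.bandpass(ecg, fs, *pp.BAND_ECG)
        ppg = pp.bandpass(ppg, fs, *pp.BAND_PPG)
        schedule = rr_schedule_from_ppg(ppg, fs)
        synth = simulate_pair(preset, schedule, fs=fs, seed=seed + i,
                              noise_frac=noise_frac)
        rr_real = rr_from_peaks(detect_peaks(ecg, fs))
        rr_syn = rr_from_peaks(detect_peaks(synth.ecg, fs))
        rep = mx.rr_metric_report(rr_real, rr_syn)
        per_record[rec.record_id] = rep.to_dict()
        rows.append(rep)
    avg = {k: float(np.mean([getattr(r, k) for r in rows]))
           for k in ("rhi", "rrmse", "remd", "kl", "ks")}
    return {"per_record": per_record, "average": avg,
            "n_records": len(rows)}
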