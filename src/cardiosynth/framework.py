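"""Dual-generator / dual-discriminator training harness and the
cross-modal inference path.

Training jointly fits a PPG generator ``G_P`` and an ECG generator
``G_E`` (each an encoder/decoder) so that (i) each reconstructs its own
modality, (ii) their latent spaces agree on paired windows (NT-Xent), and
(iii) the ECG decoded from the PPG latent fools a time-domain and a
frequency-domain (spectrogram) discriminator.  At inference only the
encoder of ``G_P`` and the decoder of ``G_E`` run: PPG in, ECG out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.signal import get_window

from .autodiff import Tensor
from .losses import LossWeights, adversarial_losses, nt_xent, smooth_l1
from .nn import (Adam, AttentionUNet1d, FreqDiscriminator, TimeDiscriminator,
                 VQVAE1d)

__all__ = [
    "GeneratorSpec", "TrainConfig", "TrainResult", "stft_spectrogram",
    "vector_quantize", "build_generator", "train", "reconstruct",
    "save_checkpoint", "load_checkpoint",
]

_LOG_EPS = 1e-7          # keeps discriminator probabilities inside (0, 1)


# --------------------------------------------------------------------------
# STFT front-end
# --------------------------------------------------------------------------

def stft_spectrogram(signal: np.ndarray, window_len: int = 128,
                     hop: int = 32) -> np.ndarray:
    """Magnitude spectrogram, Hann window, shape (frames, bins) with
    ``frames = 1 + (N - window_len) // hop`` and ``bins = window_len//2+1``."""
    signal = np.asarray(signal, dtype=float)
    if signal.size < window_len:
        raise ValueError(f"signal length {signal.size} < window {window_len}")
    win = get_window("hann", window_len)
    n_frames = 1 + (signal.size - window_len) // hop
    idx = np.arange(window_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = signal[idx] * win
    return np.abs(np.fft.rfft(frames, axis=1))


def _stft_tensor(x: Tensor, window_len: int = 128, hop: int = 32) -> Tensor:
    """Differentiable magnitude spectrogram of a (N, 1, L) tensor batch;
    the DFT is two fixed matmuls (cos / sin), magnitude smoothed at zero."""
    win = get_window("hann", window_len)
    k = np.arange(window_len // 2 + 1)
    n = np.arange(window_len)
    ang = 2.0 * np.pi * np.outer(n, k) / window_len
    cos_m = Tensor((win[:, None] * np.cos(ang)))
    sin_m = Tensor((win[:, None] * -np.sin(ang)))
    frames = x.reshape((x.shape[0], x.shape[2])).frame(window_len, hop)
    re = frames @ cos_m
    im = frames @ sin_m
    return (re * re + im * im + 1e-12).sqrt()   # (N, frames, bins)


# --------------------------------------------------------------------------
# Vector quantization (array API; the VQ generator quantizes internally)
# --------------------------------------------------------------------------

def vector_quantize(ze: np.ndarray, codebook: np.ndarray):
    """Map each latent vector to its nearest codebook entry (Euclidean);
    ties break to the lowest index.  Returns ``(zq, indices)``."""
    ze = np.atleast_2d(np.asarray(ze, dtype=float))
    codebook = np.asarray(codebook, dtype=float)
    if codebook.size == 0:
        raise ValueError("empty codebook")
    if ze.shape[1] != codebook.shape[1]:
        raise ValueError("latent and codebook dimensions differ")
    d2 = ((ze[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)
    return codebook[idx], idx


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    kind: str = "attention_unet"        # or "vqvae"
    depth: int = 3
    base_channels: int = 16
    latent_dim: int = 32
    codebook_size: int = 64
    attention: bool = True

    def __post_init__(self):
        if self.kind not in ("attention_unet", "vqvae"):
            raise ValueError("kind must be 'attention_unet' or 'vqvae'")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.kind == "vqvae" and self.codebook_size < 2:
            raise ValueError("codebook_size must be >= 2")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    window: int = 512
    lr: float = 2e-4
    lr_decay_epoch: Optional[int] = None    # step-decay point (epoch index)
    lr_decay_factor: float = 0.1
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainResult:
    checkpoint: dict
    history: list          # one dict per epoch


def build_generator(spec: GeneratorSpec, seed: int):
    if spec.kind == "vqvae":
        return VQVAE1d(depth=spec.depth, base_channels=spec.base_channels,
                       latent_dim=spec.latent_dim,
                       codebook_size=spec.codebook_size, seed=seed)
    return AttentionUNet1d(depth=spec.depth, base_channels=spec.base_channels,
                           attention=spec.attention, seed=seed)


def _clamp_prob(d: Tensor) -> Tensor:
    return d * (1.0 - 2.0 * _LOG_EPS) + _LOG_EPS


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

def train(ecg_segments: np.ndarray, ppg_segments: np.ndarray,
          config: Optional[TrainConfig] = None,
          log_path: Optional[str] = None) -> TrainResult:
    """Alternating generator/discriminator optimization of the composite
    objective on paired 512-sample ECG/PPG windows.

    The run is fully determined by ``config.seed``: model initialization,
    batch order and every update are reproducible.  With
    ``weights.beta == weights.gamma == 0`` the discriminators are disabled
    (the ablation path) and only the generation loss is optimized.
    """
    config = config or TrainConfig()
    ecg = np.asarray(ecg_segments, dtype=float)
    ppg = np.asarray(ppg_segments, dtype=float)
    if ecg.shape != ppg.shape:
        raise ValueError("ECG and PPG segment sets must be paired "
                         f"(got {ecg.shape} vs {ppg.shape})")
    if ecg.ndim != 2 or ecg.shape[1] != config.window:
        raise ValueError(f"segments must be (n, {config.window})")

    w = config.weights
    use_adv = w.beta > 0 or w.gamma > 0
    is_vq = config.generator.kind == "vqvae"
    rng = np.random.default_rng(config.seed)

    g_e = build_generator(config.generator, seed=config.seed + 1)
    g_p = build_generator(config.generator, seed=config.seed + 2)
    d_t = TimeDiscriminator(seed=config.seed + 3)
    d_f = FreqDiscriminator(seed=config.seed + 4)

    opt_g = Adam(g_e.parameters() + g_p.parameters(), lr=config.lr)
    opt_d = Adam(d_t.parameters() + d_f.parameters(), lr=config.lr)

    n = len(ecg)
    history = []
    log_rows = []
    step = 0
    for epoch in range(config.epochs):
        if config.lr_decay_epoch is not None and epoch == config.lr_decay_epoch:
            opt_g.lr *= config.lr_decay_factor
            opt_d.lr *= config.lr_decay_factor
        order = rng.permutation(n)
        sums = dict.fromkeys(
            ("contrast", "p2p", "e2e", "p2e", "l_t", "l_f", "total"), 0.0)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:       # NT-Xent needs at least one negative
                continue
            p = Tensor(ppg[idx][:, None, :])
            e = Tensor(ecg[idx][:, None, :])

            # ---------------- generator update ----------------
            zp, skips_p = g_p.encode(p)
            ze, skips_e = g_e.encode(e)
            vq_terms = None
            if is_vq:
                zq_p, _, flat_p, codes_p = g_p.quantize(zp)
                zq_e, _, flat_e, codes_e = g_e.quantize(ze)
                from .losses import vq_loss
                dict_p, com_p = vq_loss(flat_p, codes_p, lam=w.lam)
                dict_e, com_e = vq_loss(flat_e, codes_e, lam=w.lam)
                vq_terms = dict_p + com_p + dict_e + com_e
                lat_p, lat_e = zq_p, zq_e
            else:
                lat_p, lat_e = zp, ze
            p_rec = g_p.decode(lat_p, skips_p)
            e_rec = g_e.decode(lat_e, skips_e)
            e_from_p = g_e.decode(lat_p, skips_p)

            contrast = nt_xent(g_p.latent_vectors(zp),
                               g_e.latent_vectors(ze), tau=w.tau)
            l_p2p = smooth_l1(p_rec, p)
            l_e2e = smooth_l1(e_rec, e)
            l_p2e = smooth_l1(e_from_p, e)
            l_gen = contrast + l_p2p + l_e2e + l_p2e
            if vq_terms is not None:
                l_gen = l_gen + vq_terms

            total_g = w.alpha * l_gen
            if use_adv:
                # saturating form: the generator descends E[log(1 - D(fake))]
                gen_t = _clamp_prob(d_t(e_from_p))
                gen_f = _clamp_prob(d_f(_stft_tensor(e_from_p)))
                total_g = total_g + w.beta * (1.0 - gen_t).log().mean() \
                    + w.gamma * (1.0 - gen_f).log().mean()
            opt_g.zero_grad()
            total_g.backward()
            opt_g.step()

            # ---------------- discriminator update ----------------
            l_t_val = l_f_val = 0.0
            if use_adv:
                fake = Tensor(e_from_p.data)            # detached
                dr_t = _clamp_prob(d_t(e))
                df_t = _clamp_prob(d_t(fake))
                dr_f = _clamp_prob(d_f(_stft_tensor(e)))
                df_f = _clamp_prob(d_f(_stft_tensor(fake)))
                l_t, l_f = adversarial_losses(dr_t, df_t, dr_f, df_f)
                d_loss = -(l_t + l_f)                   # critic ascends
                opt_d.zero_grad()
                d_loss.backward()
                opt_d.step()
                l_t_val, l_f_val = l_t.item(), l_f.item()

            sums["contrast"] += contrast.item()
            sums["p2p"] += l_p2p.item()
            sums["e2e"] += l_e2e.item()
            sums["p2e"] += l_p2e.item()
            sums["l_t"] += l_t_val
            sums["l_f"] += l_f_val
            sums["total"] += total_g.item()
            n_batches += 1
            step += 1
            log_rows.append((step, contrast.item(), l_p2p.item(),
                             l_e2e.item(), l_p2e.item(), l_t_val, l_f_val,
                             total_g.item()))

        row = {k: v / max(n_batches, 1) for k, v in sums.items()}
        row["epoch"] = epoch
        history.append(row)

    if log_path is not None:
        header = "step,L_contrast,L_p2p,L_e2e,L_p2e,L_t,L_f,L_total"
        np.savetxt(log_path, np.asarray(log_rows), delimiter=",",
                   header=header, comments="")

    checkpoint = {
        "config": config,
        "g_e": [a.copy() for a in g_e.state_arrays()],
        "g_p": [a.copy() for a in g_p.state_arrays()],
        "d_t": [a.copy() for a in d_t.state_arrays()],
        "d_f": [a.copy() for a in d_f.state_arrays()],
    }
    return TrainResult(checkpoint=checkpoint, history=history)


def _models_from_checkpoint(checkpoint: dict):
    config: TrainConfig = checkpoint["config"]
    g_e = build_generator(config.generator, seed=config.seed + 1)
    g_p = build_generator(config.generator, seed=config.seed + 2)
    g_e.load_arrays(checkpoint["g_e"])
    g_p.load_arrays(checkpoint["g_p"])
    return g_e, g_p, config


def reconstruct(ppg_segments: np.ndarray, checkpoint: dict) -> np.ndarray:
    """PPG -> ECG inference: encoder of ``G_P`` feeding the decoder of
    ``G_E`` (for the VQ generator the latent is quantized against ``G_P``'s
    codebook in between).  Deterministic; outputs lie in [-1, 1]."""
    g_e, g_p, config = _models_from_checkpoint(checkpoint)
    ppg = np.asarray(ppg_segments, dtype=float)
    single = ppg.ndim == 1
    ppg = np.atleast_2d(ppg)
    if ppg.shape[1] != config.window:
        raise ValueError(f"segment length {ppg.shape[1]} does not match the "
                         f"training window {config.window}")
    zp, skips = g_p.encode(Tensor(ppg[:, None, :]))
    if config.generator.kind == "vqvae":
        zp, _, _, _ = g_p.quantize(zp)
    out = g_e.decode(zp, skips).data[:, 0, :]
    return out[0] if single else out


# --------------------------------------------------------------------------
# Checkpoint I/O (HDF5)
# --------------------------------------------------------------------------

def save_checkpoint(path: str, checkpoint: dict) -> None:
    import h5py

    cfg = checkpoint["config"]
    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = json.dumps(asdict(cfg))
        for part in ("g_e", "g_p", "d_t", "d_f"):
            grp = f.create_group(part)
            for i, arr in enumerate(checkpoint[part]):
                grp.create_dataset(f"w{i:04d}", data=arr)


def load_checkpoint(path: str) -> dict:
    import h5py

    with h5py.File(path, "r") as f:
        raw = json.loads(f.attrs["config_json"])
        raw["weights"] = LossWeights(**raw["weights"])
        raw["generator"] = GeneratorSpec(**raw["generator"])
        config = TrainConfig(**raw)
        ckpt = {"config": config}
        for part in ("g_e", "g_p", "d_t", "d_f"):
            grp = f[part]
            ckpt[part] = [grp[k][()] for k in sorted(grp.keys())]
    return ckpt
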