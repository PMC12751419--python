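"""The composite training objective for contrastive-adversarial
PPG-to-ECG translation.

Components: an NT-Xent contrastive loss tying the PPG encoder's latent to
the ECG encoder's latent for the same cardiac window; three smooth-L1
reconstruction losses (PPG->PPG, ECG->ECG, PPG->ECG); optional
vector-quantization dictionary + commitment terms with the stop-gradient
routing contract; and saturating adversarial value functions for a
time-domain and a frequency-domain (spectrogram) discriminator.  The
composite loss is ``alpha * L_gen + beta * L_t + gamma * L_f`` with the
defaults alpha=30, beta=3, gamma=1, tau=0.1, lambda=0.25.

All functions accept either numpy arrays (returning floats) or autodiff
tensors (returning scalar tensors ready for ``backward``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .autodiff import Tensor, astensor, stop_gradient

__all__ = [
    "LossWeights", "nt_xent", "smooth_l1", "generation_loss", "vq_loss",
    "adversarial_losses", "composite_loss", "cardiogan_plus_recon",
]


@dataclass(frozen=True)
class LossWeights:
    """Hyperparameters of the composite objective."""

    tau: float = 0.1        # contrastive temperature
    lam: float = 0.25       # VQ commitment weight
    alpha: float = 30.0     # generation-loss weight
    beta: float = 3.0       # time-domain adversarial weight
    gamma: float = 1.0      # frequency-domain adversarial weight

    def __post_init__(self):
        for name in ("tau", "lam", "alpha", "beta", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tau == 0:
            raise ValueError("tau must be strictly positive")


def _maybe_item(x: Tensor, want_tensor: bool):
    return x if want_tensor else x.item()


def nt_xent(zp, ze, tau: float = 0.1):
    """Normalized temperature-scaled cross entropy between index-aligned
    latent batches.

    For each PPG latent ``zp_i`` the positive is the ECG latent ``ze_i`` of
    the same window; all ECG latents in the batch (including the positive)
    form the softmax denominator over cosine similarities scaled by
    ``1/tau``.  Averaged over the batch.
    """
    want_tensor = isinstance(zp, Tensor) or isinstance(ze, Tensor)
    zp, ze = astensor(zp), astensor(ze)
    if zp.shape != ze.shape:
        raise ValueError("latent batches must share (N, d) shape")
    n = zp.shape[0]
    norms_p = (zp * zp).sum(axis=1, keepdims=True).sqrt()
    norms_e = (ze * ze).sum(axis=1, keepdims=True).sqrt()
    if np.any(norms_p.data == 0) or np.any(norms_e.data == 0):
        raise ValueError("zero-norm latent vector")
    zp_n = zp / norms_p
    ze_n = ze / norms_e
    sim = (zp_n @ ze_n.transpose((1, 0))) * (1.0 / tau)     # (N, N)
    pos = sim[np.arange(n), np.arange(n)]
    loss = (sim.logsumexp(axis=1) - pos).mean()
    return _maybe_item(loss, want_tensor)


def smooth_l1(x, y, beta: float = 1.0, reduction: str = "mean"):
    """Huber-style smooth-L1: quadratic inside ``beta``, linear outside."""
    want_tensor = isinstance(x, Tensor) or isinstance(y, Tensor)
    x, y = astensor(x), astensor(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    d = x - y
    ad = d.abs()
    quad = (d * d) * (0.5 / beta)
    lin = ad - 0.5 * beta
    mask = (ad.data < beta).astype(float)
    per_elem = quad * Tensor(mask) + lin * Tensor(1.0 - mask)
    if reduction == "mean":
        out = per_elem.mean()
    elif reduction == "sum":
        out = per_elem.sum()
    else:
        raise ValueError("reduction must be 'mean' or 'sum'")
    return _maybe_item(out, want_tensor)


def generation_loss(contrast, p2p, e2e, p2e, vq_terms=None,
                    lam: float = 0.25):
    """L_gen = L_contrast + L_p2p + L_e2e + L_p2e, plus
    ``dictionary + lam * commitment`` when a VQ generator is active.

    ``vq_terms`` is an optional (dictionary, commitment) pair as returned by
    :func:`vq_loss` with ``lam=1`` weighting applied here, or pre-weighted
    scalars with ``lam`` left at its default if computed elsewhere.
    """
    total = astensor(contrast) + astensor(p2p) + astensor(e2e) + astensor(p2e)
    if vq_terms is not None:
        dictionary, commitment = vq_terms
        total = total + astensor(dictionary) + lam * astensor(commitment)
    if any(isinstance(v, Tensor) for v in (contrast, p2p, e2e, p2e)):
        return total
    return total.item()


def vq_loss(ze, e, lam: float = 0.25):
    """Vector-quantization terms with the stop-gradient routing contract.

    dictionary = ||sg[ze] - e||^2 pulls the codebook toward the encoder
    output (its gradient reaches only the codebook); commitment =
    lam * ||ze - sg[e]||^2 keeps the encoder committed to its code (its
    gradient reaches only the encoder).  Returned unweighted and weighted:
    ``(dictionary, lam * commitment)``.
    """
    want_tensor = isinstance(ze, Tensor) or isinstance(e, Tensor)
    ze, e = astensor(ze), astensor(e)
    if ze.shape != e.shape:
        raise ValueError("shape mismatch between encoder output and code")
    d_dict = stop_gradient(ze) - e
    dictionary = (d_dict * d_dict).sum()
    if ze.ndim > 1:            # average per-vector squared norms over batch
        dictionary = dictionary * (1.0 / ze.shape[0])
    d_com = ze - stop_gradient(e)
    commitment = (d_com * d_com).sum()
    if ze.ndim > 1:
        commitment = commitment * (1.0 / ze.shape[0])
    commitment = lam * commitment
    if want_tensor:
        return dictionary, commitment
    return dictionary.item(), commitment.item()


def _check_probs(d):
    if np.any(d.data < 0) or np.any(d.data > 1):
        raise ValueError("discriminator outputs must lie in [0, 1]")


def adversarial_losses(d_real_t, d_fake_t, d_real_f, d_fake_f):
    """GAN value functions for the time- and frequency-domain critics.

    ``L = E[log D(real)] + E[log(1 - D(fake))]`` (natural log); the
    discriminator ascends, the generator descends the fake term.  Returns
    ``(L_t, L_f)``.
    """
    want_tensor = any(isinstance(v, Tensor)
                      for v in (d_real_t, d_fake_t, d_real_f, d_fake_f))
    out = []
    for real, fake in ((d_real_t, d_fake_t), (d_real_f, d_fake_f)):
        real, fake = astensor(real), astensor(fake)
        _check_probs(real)
        _check_probs(fake)
        l = real.log().mean() + (1.0 - fake).log().mean()
        out.append(l if want_tensor else l.item())
    return tuple(out)


def composite_loss(l_gen, l_t, l_f, weights: Optional[LossWeights] = None):
    """alpha * L_gen + beta * L_t + gamma * L_f."""
    w = weights or LossWeights()
    total = w.alpha * astensor(l_gen) + w.beta * astensor(l_t) \
        + w.gamma * astensor(l_f)
    if any(isinstance(v, Tensor) for v in (l_gen, l_t, l_f)):
        return total
    return total.item()


def cardiogan_plus_recon(p, e, g_e, g_p, beta: float = 1.0):
    """Single-loop reconstruction loss of the improved cycle-consistent
    baseline: a mid-way term ``smooth_l1(G_E(p), e)`` plus the cycle term
    ``smooth_l1(G_P(G_E(p)), p)``."""
    want_tensor = isinstance(p, Tensor) or isinstance(e, Tensor)
    p, e = astensor(p), astensor(e)
    e_hat = g_e(p)
    midway = smooth_l1(e_hat, e, beta=beta)
    cycle = smooth_l1(g_p(e_hat), p, beta=beta)
    total = astensor(midway) + astensor(cycle)
    return total if want_tensor else total.item()
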