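"""Network building blocks for the PPG-to-ECG translation framework.

Everything here runs on the package's own :mod:`~cardiosynth.autodiff`
tensors.  Two generator families are provided:

* a 1-D attention U-Net — encoder/decoder with gated skip connections, the
  default generator;
* a 1-D VQ-VAE — a convolutional encoder, a vector-quantized latent with a
  learned codebook, and a convolutional decoder.

plus two patch discriminators: a 1-D one on raw waveforms and a 2-D one on
magnitude spectrograms.  Both generators expose ``encode``/``decode`` so the
cross-modal inference path (PPG encoder feeding the ECG decoder) can be wired
without touching the unused halves.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, astensor, concat, stop_gradient

__all__ = [
    "Module", "Conv1d", "Conv2d", "InstanceNorm1d", "AttentionGate1d",
    "AttentionUNet1d", "VQVAE1d", "TimeDiscriminator", "FreqDiscriminator",
    "Adam", "attention_gate",
]


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self):
        """Flat ordered list of parameter arrays (for checkpointing)."""
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, "
                             f"model has {len(params)} parameters")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch in checkpoint")
            p.data = np.asarray(a, dtype=np.float64)


def _init(rng, *shape, fan_in):
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape),
                  requires_grad=True)


class Conv1d(Module):
    def __init__(self, cin, cout, k, stride=1, padding=0, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = _init(rng, cout, cin, k, fan_in=cin * k)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.stride, self.padding = stride, padding

    def __call__(self, x):
        return astensor(x).conv1d(self.w, self.b, self.stride, self.padding)


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, padding=0, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = _init(rng, cout, cin, k, k, fan_in=cin * k * k)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.stride, self.padding = stride, padding

    def __call__(self, x):
        return astensor(x).conv2d(self.w, self.b, self.stride, self.padding)


class InstanceNorm1d(Module):
    """Per-sample, per-channel normalization over the length axis."""

    def __init__(self, channels, eps=1e-5):
        self.gamma = Tensor(np.ones((1, channels, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1)), requires_grad=True)
        self.eps = eps

    def __call__(self, x):
        mu = x.mean(axis=2, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class _ConvBlock(Module):
    """conv -> norm -> leaky ReLU, twice."""

    def __init__(self, cin, cout, rng):
        self.c1 = Conv1d(cin, cout, 3, padding=1, rng=rng)
        self.n1 = InstanceNorm1d(cout)
        self.c2 = Conv1d(cout, cout, 3, padding=1, rng=rng)
        self.n2 = InstanceNorm1d(cout)

    def __call__(self, x):
        x = self.n1(self.c1(x)).leaky_relu(0.2)
        return self.n2(self.c2(x)).leaky_relu(0.2)


def attention_gate(skip: Tensor, gate: Tensor, wx: Conv1d, wg: Conv1d,
                   psi: Conv1d, return_coefficients: bool = False):
    """Additive attention gating of a skip connection.

    The gating signal (coarser, semantically richer) and the skip features are
    projected to a shared intermediate space, combined additively, passed
    through ReLU then a 1x1 conv + sigmoid to produce per-position
    coefficients in [0, 1] that multiplicatively re-weight the skip features.
    """
    skip, gate = astensor(skip), astensor(gate)
    if skip.shape[0] != gate.shape[0] or skip.shape[2] != gate.shape[2]:
        raise ValueError(f"misaligned shapes {skip.shape} vs {gate.shape}")
    att = psi((wx(skip) + wg(gate)).relu()).sigmoid()
    gated = skip * att
    if return_coefficients:
        return gated, att
    return gated


class AttentionGate1d(Module):
    def __init__(self, channels, gate_channels, inter_channels=None, rng=None):
        inter = inter_channels or max(channels // 2, 1)
        self.wx = Conv1d(channels, inter, 1, rng=rng)
        self.wg = Conv1d(gate_channels, inter, 1, rng=rng)
        self.psi = Conv1d(inter, 1, 1, rng=rng)
        self.last_coefficients = None

    def __call__(self, skip, gate):
        gated, att = attention_gate(skip, gate, self.wx, self.wg, self.psi,
                                    return_coefficients=True)
        self.last_coefficients = att.data
        return gated


class AttentionUNet1d(Module):
    """1-D U-Net with attention-gated skips; tanh output in [-1, 1]."""

    def __init__(self, depth=3, base_channels=16, in_channels=1,
                 out_channels=1, attention=True, seed=0):
        rng = np.random.default_rng(seed)
        self.depth, self.attention = depth, attention
        chans = [base_channels * 2 ** d for d in range(depth + 1)]
        self.enc_blocks = [_ConvBlock(in_channels if d == 0 else chans[d - 1],
                                      chans[d], rng) for d in range(depth)]
        self.down = [Conv1d(chans[d], chans[d], 4, stride=2, padding=1, rng=rng)
                     for d in range(depth)]
        self.bottleneck = _ConvBlock(chans[depth - 1], chans[depth], rng)
        self.up = [Conv1d(chans[d + 1], chans[d], 3, padding=1, rng=rng)
                   for d in range(depth)]
        self.gates = [AttentionGate1d(chans[d], chans[d], rng=rng)
                      for d in range(depth)] if attention else []
        self.dec_blocks = [_ConvBlock(2 * chans[d], chans[d], rng)
                           for d in range(depth)]
        self.head = Conv1d(chans[0], out_channels, 1, rng=rng)
        self.encode_calls = 0
        self.decode_calls = 0

    def encode(self, x):
        """Returns (latent, skips); latent is the bottleneck feature map."""
        self.encode_calls += 1
        x = astensor(x)
        skips = []
        for blk, dn in zip(self.enc_blocks, self.down):
            x = blk(x)
            skips.append(x)
            x = dn(x).leaky_relu(0.2)
        return self.bottleneck(x), skips

    def decode(self, latent, skips):
        self.decode_calls += 1
        x = latent
        for d in reversed(range(self.depth)):
            x = self.up[d](x.upsample1d(2))
            skip = skips[d]
            if self.attention:
                skip = self.gates[d](skip, x)
            x = self.dec_blocks[d](concat([skip, x], axis=1))
        return self.head(x).tanh()

    def __call__(self, x):
        latent, skips = self.encode(x)
        return self.decode(latent, skips)

    def latent_vectors(self, latent):
        """Flatten a bottleneck feature map to per-sample vectors."""
        n = latent.shape[0]
        return latent.reshape((n, int(np.prod(latent.shape[1:]))))


class VQVAE1d(Module):
    """Convolutional encoder/decoder with a vector-quantized latent."""

    def __init__(self, depth=3, base_channels=16, latent_dim=32,
                 codebook_size=64, in_channels=1, out_channels=1, seed=0):
        rng = np.random.default_rng(seed)
        self.depth, self.latent_dim = depth, latent_dim
        chans = [base_channels * 2 ** d for d in range(depth)]
        self.enc = []
        c = in_channels
        for d in range(depth):
            self.enc.append(Conv1d(c, chans[d], 4, stride=2, padding=1, rng=rng))
            c = chans[d]
        self.to_latent = Conv1d(c, latent_dim, 3, padding=1, rng=rng)
        self.codebook = Tensor(rng.normal(0, 0.5, size=(codebook_size, latent_dim)),
                               requires_grad=True)
        self.from_latent = Conv1d(latent_dim, c, 3, padding=1, rng=rng)
        self.dec = []
        for d in reversed(range(depth)):
            cout = chans[d - 1] if d > 0 else base_channels
            self.dec.append(Conv1d(chans[d], cout, 3, padding=1, rng=rng))
        self.head = Conv1d(base_channels, out_channels, 1, rng=rng)
        self.encode_calls = 0
        self.decode_calls = 0

    def encode(self, x):
        self.encode_calls += 1
        x = astensor(x)
        for conv in self.enc:
            x = conv(x).leaky_relu(0.2)
        return self.to_latent(x), []          # no skip connections

    def quantize(self, ze):
        """Nearest-codebook lookup with a straight-through gradient copy.

        Returns (zq, indices, ze_vectors, codes) where ze_vectors/codes are
        the (N*L, d) continuous and quantized vectors for the VQ losses.
        """
        n, d, l = ze.shape
        flat = ze.transpose((0, 2, 1)).reshape((n * l, d))
        dist = ((flat.data[:, None, :] - self.codebook.data[None, :, :]) ** 2).sum(-1)
        idx = dist.argmin(axis=1)              # argmin takes the lowest index on ties
        codes = self.codebook[idx]
        zq_flat = flat + stop_gradient(codes - flat)   # straight-through
        zq = zq_flat.reshape((n, l, d)).transpose((0, 2, 1))
        return zq, idx.reshape(n, l), flat, codes

    def decode(self, latent, skips=None):
        self.decode_calls += 1
        x = self.from_latent(latent).leaky_relu(0.2)
        for conv in self.dec:
            x = conv(x.upsample1d(2)).leaky_relu(0.2)
        return self.head(x).tanh()

    def __call__(self, x):
        ze, _ = self.encode(x)
        zq, _, _, _ = self.quantize(ze)
        return self.decode(zq)

    def latent_vectors(self, latent):
        n = latent.shape[0]
        return latent.reshape((n, int(np.prod(latent.shape[1:]))))


class TimeDiscriminator(Module):
    """1-D convolutional patch classifier with sigmoid outputs in (0, 1)."""

    def __init__(self, base_channels=16, depth=3, in_channels=1, seed=0):
        rng = np.random.default_rng(seed)
        self.convs = []
        c = in_channels
        for d in range(depth):
            cout = base_channels * 2 ** d
            self.convs.append(Conv1d(c, cout, 4, stride=2, padding=1, rng=rng))
            c = cout
        self.head = Conv1d(c, 1, 3, padding=1, rng=rng)

    def __call__(self, x):
        x = astensor(x)
        for conv in self.convs:
            x = conv(x).leaky_relu(0.2)
        return self.head(x).sigmoid()          # (N, 1, patches)


class FreqDiscriminator(Module):
    """2-D convolutional patch classifier on magnitude spectrograms."""

    def __init__(self, base_channels=8, depth=2, seed=0):
        rng = np.random.default_rng(seed)
        self.convs = []
        c = 1
        for d in range(depth):
            cout = base_channels * 2 ** d
            self.convs.append(Conv2d(c, cout, 3, stride=2, padding=1, rng=rng))
            c = cout
        self.head = Conv2d(c, 1, 3, padding=1, rng=rng)

    def __call__(self, spec):
        """spec: (N, frames, bins) magnitude spectrogram."""
        x = astensor(spec)
        x = x.reshape((x.shape[0], 1) + x.shape[1:])
        for conv in self.convs:
            x = conv(x).leaky_relu(0.2)
        return self.head(x).sigmoid()


class Adam:
    def __init__(self, params, lr=2e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
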