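"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients.  The op set is deliberately small — exactly
what the signal-to-signal translation networks and their losses need:
broadcast arithmetic, matmul, 1-D/2-D convolution, framing (for the
spectrogram front-end), elementwise nonlinearities and reductions.

Gradients of broadcast operations are summed back over the broadcast axes so
shapes always round-trip.  ``stop_gradient`` implements the identity-in-value
/ zero-derivative contract used by the vector-quantization losses.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "stop_gradient"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = astensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))
        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data**2, other.shape))
        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        def backward(g):
            return g @ other.data.swapaxes(-1, -2), self.data.swapaxes(-1, -2) @ g
        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)
        out._backward = backward
        return out

    # ----------------------------------------------------------- elementwise
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: (g * y,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: (g * 0.5 / y,)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: (g * (1.0 - y * y),)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: (g * y * (1.0 - y),)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: (g * mask,)
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        factor = np.where(mask, 1.0, slope)
        out = Tensor(self.data * factor, _parents=(self,))
        out._backward = lambda g: (g * factor,)
        return out

    def abs(self):
        s = np.sign(self.data)
        out = Tensor(np.abs(self.data), _parents=(self,))
        out._backward = lambda g: (g * s,)
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))
        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis=-1):
        """Numerically stable log-sum-exp along ``axis``."""
        m = self.data.max(axis=axis, keepdims=True)
        return (self - Tensor(m)).exp().sum(axis=axis).log() + Tensor(
            np.squeeze(m, axis=axis))

    # --------------------------------------------------------------- reshape
    def reshape(self, shape):
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: (g.transpose(inv),)
        return out

    def pad1d(self, left: int, right: int):
        """Zero-pad the last axis."""
        width = [(0, 0)] * (self.ndim - 1) + [(left, right)]
        out = Tensor(np.pad(self.data, width), _parents=(self,))
        def backward(g):
            sl = [slice(None)] * (self.ndim - 1) + [slice(left, g.shape[-1] - right)]
            return (g[tuple(sl)],)
        out._backward = backward
        return out

    def frame(self, length: int, hop: int):
        """Slice a (..., N) signal into overlapping frames (..., n_frames, length)."""
        n = self.shape[-1]
        n_frames = 1 + (n - length) // hop
        idx = np.arange(length)[None, :] + hop * np.arange(n_frames)[:, None]
        out = Tensor(self.data[..., idx], _parents=(self,))
        def backward(g):
            full = np.zeros_like(self.data)
            full2 = full.reshape(-1, n)
            g2 = g.reshape(-1, n_frames, length)
            for f in range(n_frames):
                full2[:, f * hop:f * hop + length] += g2[:, f, :]
            return (full,)
        out._backward = backward
        return out

    # ---------------------------------------------------------- convolutions
    def conv1d(self, weight: "Tensor", bias: "Tensor" = None,
               stride: int = 1, padding: int = 0):
        """(N, C_in, L) * (C_out, C_in, K) -> (N, C_out, L_out)."""
        x = self.pad1d(padding, padding) if padding else self
        xd = x.data
        n, c, l = xd.shape
        cout, cin, k = weight.shape
        lout = (l - k) // stride + 1
        # im2col + GEMM: one contiguous gather, one big matmul
        win = np.lib.stride_tricks.sliding_window_view(xd, k, axis=2)[:, :, ::stride, :]
        col = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            n * lout, c * k)
        w2 = weight.data.reshape(cout, cin * k)
        y = (col @ w2.T).reshape(n, lout, cout).transpose(0, 2, 1)
        parents = (x, weight) + ((bias,) if bias is not None else ())
        if bias is not None:
            y = y + bias.data[None, :, None]
        out = Tensor(y, _parents=parents)

        def backward(g):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(
                n * lout, cout)
            dw = (g2.T @ col).reshape(cout, cin, k)
            dcol = (g2 @ w2).reshape(n, lout, c, k)
            dx = np.zeros_like(xd)
            for kk in range(k):
                dx[:, :, kk:kk + stride * lout:stride] += dcol[:, :, :, kk].transpose(0, 2, 1)
            grads = (dx, dw)
            if bias is not None:
                grads = grads + (g.sum(axis=(0, 2)),)
            return grads
        out._backward = backward
        return out

    def conv2d(self, weight: "Tensor", bias: "Tensor" = None,
               stride: int = 1, padding: int = 0):
        """(N, C_in, H, W) * (C_out, C_in, Kh, Kw) -> (N, C_out, H_out, W_out)."""
        if padding:
            pd = [(0, 0), (0, 0), (padding, padding), (padding, padding)]
            xp = Tensor(np.pad(self.data, pd), _parents=(self,))
            def unpad(g):
                return (g[:, :, padding:g.shape[2] - padding,
                           padding:g.shape[3] - padding],)
            xp._backward = unpad
        else:
            xp = self
        xd = xp.data
        n, c, h, w = xd.shape
        cout, cin, kh, kw = weight.shape
        hout = (h - kh) // stride + 1
        wout = (w - kw) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(xd, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride, :, :]
        col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * hout * wout, cin * kh * kw)
        w2 = weight.data.reshape(cout, cin * kh * kw)
        y = (col @ w2.T).reshape(n, hout, wout, cout).transpose(0, 3, 1, 2)
        parents = (xp, weight) + ((bias,) if bias is not None else ())
        if bias is not None:
            y = y + bias.data[None, :, None, None]
        out = Tensor(y, _parents=parents)

        def backward(g):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(
                n * hout * wout, cout)
            dw = (g2.T @ col).reshape(cout, cin, kh, kw)
            dcol = (g2 @ w2).reshape(n, hout, wout, cin, kh, kw)
            dx = np.zeros_like(xd)
            for jj in range(kh):
                for kk in range(kw):
                    dx[:, :, jj:jj + stride * hout:stride,
                       kk:kk + stride * wout:stride] += \
                        dcol[:, :, :, :, jj, kk].transpose(0, 3, 1, 2)
            grads = (dx, dw)
            if bias is not None:
                grads = grads + (g.sum(axis=(0, 2, 3)),)
            return grads
        out._backward = backward
        return out

    def upsample1d(self, factor: int):
        """Nearest-neighbour upsampling along the last axis."""
        out = Tensor(np.repeat(self.data, factor, axis=-1), _parents=(self,))
        def backward(g):
            shp = g.shape[:-1] + (self.shape[-1], factor)
            return (g.reshape(shp).sum(axis=-1),)
        out._backward = backward
        return out

    # ---------------------------------------------------------------- engine
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)
        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if not t._parents:
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def stop_gradient(x: Tensor) -> Tensor:
    """Identity in value, zero derivative (the ``sg`` operator)."""
    x = astensor(x)
    return Tensor(x.data.copy())


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out
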