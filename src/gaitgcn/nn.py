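"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module provides the tensor engine used by the adaptive-trimming
network, the adaptive graph-convolutional backbone and the multi-task
heads.  It implements exactly the operations those models need — dense
and 1-D convolutional layers, pooling, softmax-family ops, a
differentiable temporal crop-resampler — together with an Adam
optimizer.  Everything is float32 and single-threaded numpy; gradients
are accumulated by topologically-ordered backward closures.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes that were added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=""):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # ------------------------------------------------------------------ #
    # graph traversal
    # ------------------------------------------------------------------ #
    def backward(self, grad=None):
        if grad is None:
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
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=DTYPE)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if not self.requires_grad:
            return
        grad = np.asarray(grad, dtype=DTYPE)
        self.grad = grad if self.grad is None else self.grad + grad

    # ------------------------------------------------------------------ #
    # arithmetic
    # ------------------------------------------------------------------ #
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        inv = 1.0 / other.data
        out_data = self.data * inv

        def bwd(g):
            self._accum(_unbroadcast(g * inv, self.data.shape))
            other._accum(_unbroadcast(-g * out_data * inv, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __pow__(self, p: float):
        out_data = self.data**p

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bwd(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    # ------------------------------------------------------------------ #
    # shape ops
    # ------------------------------------------------------------------ #
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def bwd(g):
            self._accum(g.reshape(orig))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor(out_data, parents=(self,), backward=bwd)

    # ------------------------------------------------------------------ #
    # reductions
    # ------------------------------------------------------------------ #
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------- #
# elementwise nonlinearities
# ---------------------------------------------------------------------- #
def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def bwd(g):
        x._accum(g * mask)

    return Tensor(out_data, parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x._accum(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=bwd)


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)

    def bwd(g):
        x._accum(g * e)

    return Tensor(e, parents=(x,), backward=bwd)


def log(x: Tensor) -> Tensor:
    def bwd(g):
        x._accum(g / x.data)

    return Tensor(np.log(x.data), parents=(x,), backward=bwd)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Hard clip; gradient passes only where the input is inside [lo, hi]."""
    mask = (x.data >= lo) & (x.data <= hi)

    def bwd(g):
        x._accum(g * mask)

    return Tensor(np.clip(x.data, lo, hi), parents=(x,), backward=bwd)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def bwd(g):
        x._accum(g * (1.0 - t * t))

    return Tensor(t, parents=(x,), backward=bwd)


def rms_norm(x: Tensor, eps: float = 1e-6) -> Tensor:
    """Scale each row of x (..., D) to unit root-mean-square.

    Keeps the magnitude of pooled features independent of the data
    distribution so the prediction heads always start in the same
    regime.
    """
    D = x.data.shape[-1]
    r = np.sqrt((x.data**2).mean(axis=-1, keepdims=True) + eps)
    y = x.data / r

    def bwd(g):
        s = (g * y).mean(axis=-1, keepdims=True)
        x._accum((g - y * s) / r)

    return Tensor(y, parents=(x,), backward=bwd)


def soft_bound(x: Tensor, lo: float, hi: float) -> Tensor:
    """Smoothly saturate x into (lo, hi), identity-like near zero.

    Uses hi*tanh(x/hi) for x >= 0 and |lo|*tanh(x/|lo|) for x < 0, so
    f(0) = 0, f'(0) = 1, and gradients never vanish exactly (unlike a
    hard clip, which freezes parameters stuck outside the window).
    Requires lo < 0 < hi.
    """
    if not lo < 0 < hi:
        raise ValueError("soft_bound requires lo < 0 < hi")
    a, b = hi, -lo
    pos = x.data >= 0
    tp = np.tanh(x.data / a)
    tn = np.tanh(x.data / b)
    out_data = np.where(pos, a * tp, b * tn)

    def bwd(g):
        grad = np.where(pos, 1.0 - tp * tp, 1.0 - tn * tn)
        x._accum(g * grad)

    return Tensor(out_data, parents=(x,), backward=bwd)


# ---------------------------------------------------------------------- #
# softmax family (numerically stabilized)
# ---------------------------------------------------------------------- #
def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    return Tensor(s, parents=(x,), backward=bwd)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    s = np.exp(out)

    def bwd(g):
        x._accum(g - s * g.sum(axis=axis, keepdims=True))

    return Tensor(out, parents=(x,), backward=bwd)


def logsumexp(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    se = e.sum(axis=axis, keepdims=True)
    out = (m + np.log(se)).squeeze(axis)
    soft = e / se

    def bwd(g):
        x._accum(np.expand_dims(g, axis) * soft)

    return Tensor(out, parents=(x,), backward=bwd)


# ---------------------------------------------------------------------- #
# structured ops
# ---------------------------------------------------------------------- #
def linear(x: Tensor, W: Tensor, b: Tensor | None = None) -> Tensor:
    """x: (..., Cin) @ W: (Cin, Cout) + b."""
    out = x @ W
    if b is not None:
        out = out + b
    return out


def channel_map(f: Tensor, W: Tensor) -> Tensor:
    """1x1 convolution over the channel axis of f: (B, Cin, T, N) -> (B, Cout, T, N).

    W has shape (Cout, Cin).  Implemented as one batched GEMM over the
    flattened (T, N) axes.
    """
    B, C, T, N = f.data.shape
    O = W.data.shape[0]
    f2 = np.ascontiguousarray(f.data).reshape(B, C, T * N)
    out_data = np.matmul(W.data, f2).reshape(B, O, T, N)

    def bwd(g):
        g2 = np.ascontiguousarray(g).reshape(B, O, T * N)
        W._accum(np.tensordot(g2, f2, axes=([0, 2], [0, 2])))
        f._accum(np.matmul(W.data.T, g2).reshape(B, C, T, N))

    return Tensor(out_data, parents=(f, W), backward=bwd)


def conv1d(x: Tensor, W: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded temporal convolution.

    x: (B, Cin, T); W: (Cout, Cin, K) with K odd; b: (Cout,).
    Implemented as K shifted batched matmuls (K is small: 3 or 5).
    """
    B, Cin, T = x.data.shape
    Cout, Cin2, K = W.data.shape
    if Cin != Cin2:
        raise ValueError(f"conv1d channel mismatch: {Cin} vs {Cin2}")
    pad = (K - 1) // 2
    xp = np.zeros((B, Cin, T + 2 * pad), dtype=DTYPE)
    xp[:, :, pad : pad + T] = x.data
    out_data = np.zeros((B, Cout, T), dtype=DTYPE)
    for k in range(K):
        out_data += np.matmul(W.data[:, :, k], xp[:, :, k : k + T])
    if b is not None:
        out_data += b.data.reshape(1, Cout, 1)

    def bwd(g):
        gxp = np.zeros_like(xp)
        gW = np.zeros_like(W.data)
        for k in range(K):
            seg = xp[:, :, k : k + T]
            gW[:, :, k] = np.tensordot(g, seg, axes=([0, 2], [0, 2]))
            gxp[:, :, k : k + T] += np.matmul(W.data[:, :, k].T, g)
        x._accum(gxp[:, :, pad : pad + T])
        W._accum(gW)
        if b is not None:
            b._accum(g.sum(axis=(0, 2)))

    parents = (x, W) if b is None else (x, W, b)
    return Tensor(out_data, parents=parents, backward=bwd)


def max_pool1d(x: Tensor, factor: int = 2) -> Tensor:
    """Temporal max pooling over the last axis; T must be divisible by factor."""
    *lead, T = x.data.shape
    if T % factor:
        raise ValueError(f"temporal length {T} not divisible by pool factor {factor}")
    if factor == 2:  # fast path: elementwise compare, no argmax/scatter
        r = x.data.reshape(*lead, T // 2, 2)
        left, right = r[..., 0], r[..., 1]
        mask = left >= right
        out_data = np.where(mask, left, right)

        def bwd2(g):
            gr = np.empty_like(r)
            gr[..., 0] = np.where(mask, g, 0.0)
            gr[..., 1] = np.where(mask, 0.0, g)
            x._accum(gr.reshape(x.data.shape))

        return Tensor(out_data, parents=(x,), backward=bwd2)
    r = x.data.reshape(*lead, T // factor, factor)
    arg = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, arg[..., None], axis=-1).squeeze(-1)

    def bwd(g):
        gr = np.zeros_like(r)
        np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
        x._accum(gr.reshape(x.data.shape))

    return Tensor(out_data, parents=(x,), backward=bwd)


def crop_resample(x: Tensor, s: Tensor, e: Tensor, out_len: int) -> Tensor:
    """Differentiable temporal crop: uniformly resample x on [s, e].

    x: (B, CH, T); s, e: (B,) continuous sample indices with 0 < s < e < T.
    Places `out_len` grid points uniformly on [s, e] and samples each by
    linear interpolation between neighbouring frames.  Gradients flow to
    s and e (and to x when required), as in a 1-D spatial-transformer
    sampler.
    """
    if out_len < 2:
        raise ValueError("out_len must be >= 2")
    B, CH, T = x.data.shape
    frac_j = np.linspace(0.0, 1.0, out_len, dtype=DTYPE)  # (L,)
    grid = s.data[:, None] + (e.data - s.data)[:, None] * frac_j[None, :]  # (B, L)
    gc = np.clip(grid, 0.0, float(T - 1))
    i0 = np.minimum(np.floor(gc), T - 2).astype(np.int64)  # (B, L)
    frac = np.clip(gc - i0, 0.0, 1.0).astype(DTYPE)
    idx0 = i0[:, None, :]  # (B, 1, L) broadcast over channels
    x0 = np.take_along_axis(x.data, np.broadcast_to(idx0, (B, CH, out_len)), axis=2)
    x1 = np.take_along_axis(
        x.data, np.broadcast_to(idx0 + 1, (B, CH, out_len)), axis=2
    )
    out_data = x0 * (1.0 - frac[:, None, :]) + x1 * frac[:, None, :]

    def bwd(g):
        # d out / d grid = x1 - x0 (zero where the grid was clipped)
        inside = ((grid >= 0.0) & (grid <= float(T - 1))).astype(DTYPE)
        dgrid = ((x1 - x0) * g).sum(axis=1) * inside  # (B, L)
        s._accum((dgrid * (1.0 - frac_j[None, :])).sum(axis=1))
        e._accum((dgrid * frac_j[None, :]).sum(axis=1))
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            w0 = g * (1.0 - frac[:, None, :])
            w1 = g * frac[:, None, :]
            bidx = np.arange(B)[:, None, None]
            cidx = np.arange(CH)[None, :, None]
            np.add.at(gx, (bidx, cidx, np.broadcast_to(idx0, g.shape)), w0)
            np.add.at(gx, (bidx, cidx, np.broadcast_to(idx0 + 1, g.shape)), w1)
            x._accum(gx)

    return Tensor(out_data, parents=(x, s, e), backward=bwd)


# ---------------------------------------------------------------------- #
# parameters and optimization
# ---------------------------------------------------------------------- #
class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data, name=""):
        super().__init__(data, requires_grad=True, name=name)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Adam:
    """Adam with fixed learning rate (the training protocol uses lr 1e-3)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
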