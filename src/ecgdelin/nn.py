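"""A small reverse-mode automatic-differentiation engine on numpy arrays.

This module provides exactly the primitives the 1D segmentation network
needs: convolution (stride 1, zero padding), max pooling by 2, average
pooling by integer factors, linear-interpolation upsampling, batch
normalization, leaky ReLU, dropout, channel concatenation, softmax and the
usual elementwise/reduction arithmetic — each with an analytic backward
pass, verified against finite differences in the test suite.  An Adam
optimizer and a cosine-annealing learning-rate schedule complete the
training toolkit.

Array layout is ``(batch, channels, length)`` for all feature maps.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import sparse

Array = np.ndarray

#: Default dtype for tensors and parameters.  float32 is the working
#: precision (ample for a segmentation network and twice as fast on BLAS);
#: tests switch to float64 for finite-difference gradient verification.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype).type


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence[tuple["Tensor", Callable[[Array], Array]]] = ()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[Array] = None
        self._parents = tuple(p for p in parents if p[0].requires_grad)
        self.requires_grad = requires_grad or bool(self._parents)

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ---------------------------------------------------

    def backward(self, grad: Optional[Array] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=DTYPE)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, fn in node._parents:
                contrib = fn(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + contrib
                else:
                    grads[key] = contrib
        # leaves reached through several paths accumulate via grads dict; any
        # leaf left in grads (shared parents) is flushed here
        for node in topo:
            g = grads.pop(id(node), None)
            if g is not None and not node._parents:
                node.grad = g if node.grad is None else node.grad + g

    # -- arithmetic --------------------------------------------------------

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = fwd(self.data, other.data)
        return Tensor(out_data, parents=[
            (self, lambda g: _unbroadcast(bwd_self(g, self.data, other.data), self.data.shape)),
            (other, lambda g: _unbroadcast(bwd_other(g, self.data, other.data), other.data.shape)),
        ])

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b, lambda g, a, b: -g * a / (b * b))

    def __neg__(self):
        return Tensor(-self.data, parents=[(self, lambda g: -g)])

    def __pow__(self, exponent: float):
        data = self.data ** exponent
        return Tensor(data, parents=[
            (self, lambda g: g * exponent * self.data ** (exponent - 1.0))
        ])

    def log(self) -> "Tensor":
        return Tensor(np.log(self.data), parents=[(self, lambda g: g / self.data)])

    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return Tensor(out, parents=[(self, lambda g: g * out)])

    def clip_min(self, floor: float) -> "Tensor":
        keep = self.data > floor
        return Tensor(np.maximum(self.data, floor),
                      parents=[(self, lambda g: g * keep)])

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g: Array) -> Array:
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        return Tensor(out, parents=[(self, bwd)])

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        return Tensor(self.data.reshape(*shape),
                      parents=[(self, lambda g: g.reshape(orig))])


# ---------------------------------------------------------------------------
# Neural-network primitives
# ---------------------------------------------------------------------------


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    pos = x.data > 0
    out = np.where(pos, x.data, slope * x.data)
    return Tensor(out, parents=[(x, lambda g: g * np.where(pos, 1.0, slope))])


def conv1d(x: Tensor, w: Tensor, b: Optional[Tensor], pad: int) -> Tensor:
    """1-D convolution, stride 1, zero padding; x (N,C,L), w (O,C,K).

    Implemented as one transpose to time-major layout plus K strided GEMMs
    (one per kernel tap), which BLAS handles without materializing patch
    matrices; the backward passes reuse the same trick.
    """
    k = w.data.shape[2]
    n, c, L = x.data.shape
    o = w.data.shape[0]
    lout = L + 2 * pad - k + 1
    # time-major padded input (N, Lp, C), built once and reused in backward
    xp2 = np.zeros((n, L + 2 * pad, c), dtype=x.data.dtype)
    xp2[:, pad: pad + L, :] = x.data.transpose(0, 2, 1)
    wt = [np.ascontiguousarray(w.data[:, :, t].T) for t in range(k)]  # (C, O) each

    y2 = xp2[:, 0:lout, :] @ wt[0]
    for t in range(1, k):
        y2 += xp2[:, t: t + lout, :] @ wt[t]
    out = y2.transpose(0, 2, 1)
    if b is not None:
        out = out + b.data[None, :, None]

    def bwd_x(g: Array) -> Array:
        g2 = np.ascontiguousarray(g.transpose(0, 2, 1))  # (N, Lout, O)
        dxp2 = np.zeros_like(xp2)
        for t in range(k):
            dxp2[:, t: t + lout, :] += g2 @ wt[t].T
        return dxp2[:, pad: pad + L, :].transpose(0, 2, 1)

    def bwd_w(g: Array) -> Array:
        g2 = np.ascontiguousarray(g.transpose(0, 2, 1))  # (N, Lout, O)
        dw = np.empty_like(w.data)
        for t in range(k):
            # contract over batch and time: (C, O) = sum_n v_t[n].T @ g2[n]
            dw[:, :, t] = np.matmul(xp2[:, t: t + lout, :].transpose(0, 2, 1), g2).sum(axis=0).T
        return dw

    parents = [(x, bwd_x), (w, bwd_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2))))
    return Tensor(out, parents=parents)


def maxpool2(x: Tensor) -> Tensor:
    n, c, L = x.data.shape
    if L % 2:
        raise ValueError("maxpool2 requires even length")
    xr = x.data.reshape(n, c, L // 2, 2)
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def bwd(g: Array) -> Array:
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=3)
        return dxr.reshape(n, c, L)

    return Tensor(out, parents=[(x, bwd)])


def avgpool(x: Tensor, factor: int) -> Tensor:
    n, c, L = x.data.shape
    if L % factor:
        raise ValueError(f"length {L} not divisible by pool factor {factor}")
    out = x.data.reshape(n, c, L // factor, factor).mean(axis=3)

    def bwd(g: Array) -> Array:
        return np.repeat(g, factor, axis=2) / factor

    return Tensor(out, parents=[(x, bwd)])


_interp_cache: dict[tuple[int, int, str], sparse.csr_matrix] = {}


def _interp_matrix(l_in: int, l_out: int) -> sparse.csr_matrix:
    """Sparse (l_out, l_in) linear-interpolation matrix (endpoints aligned)."""
    key = (l_in, l_out, np.dtype(DTYPE).name)
    mat = _interp_cache.get(key)
    if mat is None:
        src = np.linspace(0.0, l_in - 1.0, l_out) if l_out > 1 else np.zeros(1)
        i0 = np.clip(np.floor(src).astype(int), 0, l_in - 1)
        i1 = np.clip(i0 + 1, 0, l_in - 1)
        w1 = src - i0
        rows = np.repeat(np.arange(l_out), 2)
        cols = np.stack([i0, i1], axis=1).reshape(-1)
        vals = np.stack([1.0 - w1, w1], axis=1).reshape(-1).astype(DTYPE)
        mat = sparse.csr_matrix((vals, (rows, cols)), shape=(l_out, l_in))
        _interp_cache[key] = mat
    return mat


def upsample_linear(x: Tensor, l_out: int) -> Tensor:
    n, c, l_in = x.data.shape
    mat = _interp_matrix(l_in, l_out)
    out = (mat @ x.data.reshape(n * c, l_in).T).T.reshape(n, c, l_out)

    def bwd(g: Array) -> Array:
        return (mat.T @ g.reshape(n * c, l_out).T).T.reshape(n, c, l_in)

    return Tensor(out, parents=[(x, bwd)])


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_bwd(i: int):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor(out, parents=[(t, make_bwd(i)) for i, t in enumerate(tensors)])


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = ((rng.uniform(size=x.data.shape) >= p) / (1.0 - p)).astype(DTYPE)
    return Tensor(x.data * keep, parents=[(x, lambda g: g * keep)])


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def bwd(g: Array) -> Array:
        dot = (g * out).sum(axis=axis, keepdims=True)
        return out * (g - dot)

    return Tensor(out, parents=[(x, bwd)])


def gather_channel(x: Tensor, labels: Array) -> Tensor:
    """Select x[n, labels[n, l], l] -> (N, L); labels is an int array."""
    n, c, L = x.data.shape
    idx = labels[:, None, :]
    out = np.take_along_axis(x.data, idx, axis=1)[:, 0, :]

    def bwd(g: Array) -> Array:
        dx = np.zeros_like(x.data)
        np.put_along_axis(dx, idx, g[:, None, :], axis=1)
        return dx

    return Tensor(out, parents=[(x, bwd)])


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Conv1d:
    """Stride-1 1-D convolution layer with He-normal weight init."""

    def __init__(self, c_in: int, c_out: int, kernel: int, pad: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel
        std = math.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, (c_out, c_in, kernel)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.pad = (kernel - 1) // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, self.pad)

    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class BatchNorm1d:
    """Per-channel batch normalization over (batch, length).

    Batch statistics during training, exponential running averages at
    inference.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mean = x.data.mean(axis=(0, 2))
            var = x.data.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None]) * inv[None, :, None]
        out = xhat * self.gamma.data[None, :, None] + self.beta.data[None, :, None]

        m = x.data.shape[0] * x.data.shape[2]

        def bwd_x(g: Array) -> Array:
            gxh = g * self.gamma.data[None, :, None]
            if not training:
                return gxh * inv[None, :, None]
            sum_g = gxh.sum(axis=(0, 2))
            sum_gx = (gxh * xhat).sum(axis=(0, 2))
            return (inv[None, :, None] / m) * (
                m * gxh - sum_g[None, :, None] - xhat * sum_gx[None, :, None]
            )

        return Tensor(out, parents=[
            (x, bwd_x),
            (self.gamma, lambda g: (g * xhat).sum(axis=(0, 2))),
            (self.beta, lambda g: g.sum(axis=(0, 2))),
        ])

    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------


class Adam:
    """Adam with the customary default moments (beta1 0.9, beta2 0.999)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(step: int, total_steps: int, lr_init: float, lr_min: float = 0.0) -> float:
    """Single-cycle cosine annealing from ``lr_init`` to ``lr_min``.

    ``step`` runs from 0 (returns ``lr_init``) to ``total_steps - 1``
    (returns ``lr_min``).
    """
    if total_steps <= 1:
        return lr_init
    frac = step / (total_steps - 1)
    return lr_min + 0.5 * (lr_init - lr_min) * (1.0 + math.cos(math.pi * frac))
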