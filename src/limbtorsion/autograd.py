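"""Minimal reverse-mode automatic differentiation over numpy arrays.

This engine exists to train the volumetric segmentation network on CPU.  It
implements exactly the primitives that network needs — elementwise arithmetic,
reductions, ReLU, log-softmax, 3x3x3 and 1x1x1 convolutions, instance
normalization, max-pooling, separable linear (trilinear) upsampling and
channel concatenation — each with a hand-written backward pass.  Everything is
float32; a single sample is processed at a time (batch size one), so feature
maps are laid out ``(channels, x, y, z)`` without a batch axis.

Convolutions use a shift-and-matmul scheme: the padded input is shifted by
each of the 27 kernel offsets and multiplied against the corresponding kernel
slice.  This keeps peak memory at one feature map per offset instead of a full
im2col buffer, while still routing all heavy work through BLAS.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "relu", "exp", "tsum",
    "log_softmax", "conv3x3", "conv1x1", "instance_norm",
    "maxpool", "upsample_linear", "concat", "backward",
]


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # graph-building operator sugar (constants may be floats or ndarrays)
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return div(self, other)
        return mul(self, 1.0 / np.asarray(other, dtype=np.float32))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence[Tensor],
          backward_fn: Callable[[np.ndarray], None]) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise and reductions


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data

    def bw(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _node(out, (a, b), bw)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data - b.data

    def bw(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(-g, b.data.shape))

    return _node(out, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data

    def bw(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(out, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data / b.data

    def bw(g):
        _accumulate(a, _unbroadcast(g / b.data, a.data.shape))
        _accumulate(b, _unbroadcast(-g * out / b.data, b.data.shape))

    return _node(out, (a, b), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, 0.0).astype(np.float32)

    def bw(g):
        _accumulate(x, g * mask)

    return _node(out, (x,), bw)


def exp(x: Tensor) -> Tensor:
    out = np.exp(x.data)

    def bw(g):
        _accumulate(x, g * out)

    return _node(out, (x,), bw)


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        g = np.asarray(g, dtype=np.float32)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accumulate(x, np.broadcast_to(g, x.data.shape))

    return _node(np.asarray(out, dtype=np.float32), (x,), bw)


def log_softmax(x: Tensor, axis: int = 0) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    s = x.data - m
    lse = np.log(np.exp(s).sum(axis=axis, keepdims=True))
    out = s - lse
    soft = np.exp(out)

    def bw(g):
        _accumulate(x, g - soft * g.sum(axis=axis, keepdims=True))

    return _node(out, (x,), bw)


# ---------------------------------------------------------------------------
# convolutions

_OFFSETS = [(di, dj, dk) for di in range(3) for dj in range(3) for dk in range(3)]


def _pad_spatial(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))


def conv3x3(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-size 3x3x3 convolution, zero padded; ``w`` is ``(F, C, 3, 3, 3)``.

    Uses an explicit im2col buffer so both the forward pass and the two
    backward passes are single BLAS GEMMs; the buffer is kept alive for the
    backward pass (memory for speed).
    """
    C, X, Y, Z = x.data.shape
    F = w.data.shape[0]
    if w.data.shape[1] != C:
        raise ValueError(f"kernel expects {w.data.shape[1]} channels, input has {C}")
    N = X * Y * Z
    xp = _pad_spatial(x.data)
    cols = np.empty((C, 27, X, Y, Z), dtype=np.float32)
    for k, (di, dj, dk) in enumerate(_OFFSETS):
        cols[:, k] = xp[:, di:di + X, dj:dj + Y, dk:dk + Z]
    cols2 = cols.reshape(C * 27, N)
    W2 = w.data.reshape(F, C * 27)
    out = W2 @ cols2
    out += b.data[:, None]

    def bw(g):
        g2 = np.ascontiguousarray(g).reshape(F, N)
        _accumulate(b, g2.sum(axis=1))
        _accumulate(w, (g2 @ cols2.T).reshape(w.data.shape))
        if x.requires_grad:
            dcols = (W2.T @ g2).reshape(C, 27, X, Y, Z)
            dxp = np.zeros_like(xp)
            for k, (di, dj, dk) in enumerate(_OFFSETS):
                dxp[:, di:di + X, dj:dj + Y, dk:dk + Z] += dcols[:, k]
            _accumulate(x, dxp[:, 1:-1, 1:-1, 1:-1])

    return _node(out.reshape(F, X, Y, Z), (x, w, b), bw)


def conv1x1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Pointwise channel-mixing convolution; ``w`` is ``(F, C)``."""
    C = x.data.shape[0]
    spatial = x.data.shape[1:]
    F = w.data.shape[0]
    x2 = x.data.reshape(C, -1)
    out = (w.data @ x2 + b.data[:, None]).reshape(F, *spatial)

    def bw(g):
        g2 = g.reshape(F, -1)
        _accumulate(b, g2.sum(axis=1))
        _accumulate(w, g2 @ x2.T)
        if x.requires_grad:
            _accumulate(x, (w.data.T @ g2).reshape(x.data.shape))

    return _node(out, (x, w, b), bw)


# ---------------------------------------------------------------------------
# normalization, pooling, upsampling, concat


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel standardization over the spatial axes (single sample)."""
    C = x.data.shape[0]
    x2 = x.data.reshape(C, -1)
    mu = x2.mean(axis=1, keepdims=True)
    var = x2.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x2 - mu) * inv
    out = (gamma.data[:, None] * xhat + beta.data[:, None]).reshape(x.data.shape)

    def bw(g):
        g2 = g.reshape(C, -1)
        _accumulate(beta, g2.sum(axis=1))
        _accumulate(gamma, (g2 * xhat).sum(axis=1))
        if x.requires_grad:
            dxhat = g2 * gamma.data[:, None]
            m1 = dxhat.mean(axis=1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
            _accumulate(x, (inv * (dxhat - m1 - xhat * m2)).reshape(x.data.shape))

    return _node(out, (x, gamma, beta), bw)


def maxpool(x: Tensor, factors: tuple[int, int, int]) -> Tensor:
    C, X, Y, Z = x.data.shape
    fx, fy, fz = factors
    if X % fx or Y % fy or Z % fz:
        axis = "xyz"[[X % fx, Y % fy, Z % fz].index(
            next(v for v in (X % fx, Y % fy, Z % fz) if v))]
        raise ValueError(f"axis {axis} (shape {(X, Y, Z)}) not divisible by pooling {factors}")
    Xo, Yo, Zo = X // fx, Y // fy, Z // fz
    win = fx * fy * fz
    blocks = np.ascontiguousarray(
        x.data.reshape(C, Xo, fx, Yo, fy, Zo, fz).transpose(0, 1, 3, 5, 2, 4, 6)
    ).reshape(C, Xo, Yo, Zo, win)
    arg = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        db = np.zeros((C, Xo, Yo, Zo, win), dtype=np.float32)
        np.put_along_axis(db, arg[..., None], g[..., None], axis=-1)
        dx = db.reshape(C, Xo, Yo, Zo, fx, fy, fz).transpose(0, 1, 4, 2, 5, 3, 6)
        _accumulate(x, np.ascontiguousarray(dx).reshape(C, X, Y, Z))

    return _node(out, (x,), bw)


@lru_cache(maxsize=None)
def _upsample_matrix(n: int) -> np.ndarray:
    """Dense 1D linear x2 interpolation operator (2n x n), centre-aligned.

    Output sample i maps to source coordinate (i + 0.5)/2 - 0.5, clamped at the
    edges; applying it along each upsampled axis yields trilinear upsampling.
    """
    U = np.zeros((2 * n, n), dtype=np.float32)
    for i in range(2 * n):
        src = (i + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n - 1)
        hi_c = min(max(lo + 1, 0), n - 1)
        U[i, lo_c] += 1.0 - frac
        U[i, hi_c] += frac
    return U


def _apply_axis(arr: np.ndarray, M: np.ndarray, axis: int) -> np.ndarray:
    out = np.tensordot(M, arr, axes=([1], [axis]))
    return np.ascontiguousarray(np.moveaxis(out, 0, axis))


def upsample_linear(x: Tensor, factors: tuple[int, int, int]) -> Tensor:
    """Separable linear (trilinear) upsampling by per-axis factors in {1, 2}."""
    if any(f not in (1, 2) for f in factors):
        raise ValueError("upsampling factors must be 1 or 2 per axis")
    out = x.data
    mats: list[tuple[int, np.ndarray]] = []
    for ax, f in enumerate(factors):
        if f == 2:
            M = _upsample_matrix(out.shape[ax + 1])
            out = _apply_axis(out, M, ax + 1)
            mats.append((ax + 1, M))

    def bw(g):
        for ax, M in reversed(mats):
            g = _apply_axis(g, M.T, ax)
        _accumulate(x, g)

    return _node(out, (x,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        start = 0
        for t, n in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + n)
            _accumulate(t, g[tuple(sl)])
            start += n

    return _node(out, tuple(tensors), bw)


# ---------------------------------------------------------------------------
# backprop driver


def backward(loss: Tensor) -> None:
    """Run reverse-mode accumulation from a scalar loss."""
    if loss.data.size != 1:
        raise ValueError("backward expects a scalar loss")
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
            # free intermediate gradients to bound peak memory
            if node is not loss:
                node.grad = None
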