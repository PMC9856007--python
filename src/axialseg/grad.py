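"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the tensor backend for the segmentation network: a small tape-based
autograd with exactly the primitives the model needs — broadcast arithmetic,
batched matmul, axis shuffling, 3-D convolution (arbitrary odd kernel, stride,
zero padding), 2x transposed convolution, nearest-neighbour upsampling, and the
pointwise nonlinearities. Everything is float32.

Gradients for every primitive are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        # first contribution is kept by reference (backwards never mutate g);
        # later contributions allocate a fresh sum, so aliasing stays safe
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the tape as we go
            node._backward = None
            node._parents = ()

    # -- operator sugar ---------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        return mul(self, power(as_tensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- elementwise / reductions ---------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** np.float32(p)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** np.float32(p - 1))

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return _make(data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through the un-clamped region."""
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)
    mask = ((a.data > lo) & (a.data < hi)).astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = as_tensor(a)
    pos = a.data > 0
    data = np.where(pos, a.data, slope * a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * np.where(pos, 1.0, slope).astype(np.float32))

    return _make(data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * data).sum(axis=axis, keepdims=True)
            a._accumulate(data * (g - dot))

    return _make(data, (a,), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


# -- shape ops -------------------------------------------------------------


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    return _make(data, (a,), backward)


def transpose(a, axes: Sequence[int]) -> Tensor:
    a = as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return _make(data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, part in zip(ts, parts):
            if t.requires_grad:
                t._accumulate(part)

    return _make(data, tuple(ts), backward)


def matmul(a, b) -> Tensor:
    """Batched matrix product on the last two axes."""
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ b.data.swapaxes(-1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = a.data.swapaxes(-1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return _make(data, (a, b), backward)


# -- spatial ops -----------------------------------------------------------


def _corr3d(xdata: np.ndarray, wdata: np.ndarray, stride: int, padding: int,
            return_cols: bool = False):
    """im2col + GEMM cross-correlation core (no autodiff bookkeeping)."""
    n, c, d, h, wd = xdata.shape
    o, _, k = wdata.shape[:3]
    p, s = padding, stride
    xp = np.pad(xdata, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else xdata
    do = (d + 2 * p - k) // s + 1
    ho = (h + 2 * p - k) // s + 1
    wo = (wd + 2 * p - k) // s + 1
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    view = view[:, :, ::s, ::s, ::s]  # (N, C, Do, Ho, Wo, k, k, k)
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 4, 1, 5, 6, 7))
    cols = cols.reshape(n * do * ho * wo, c * k ** 3)
    out = cols @ wdata.reshape(o, -1).T
    out = np.ascontiguousarray(out.reshape(n, do, ho, wo, o).transpose(0, 4, 1, 2, 3))
    return (out, cols) if return_cols else out


def conv3d(x, w, stride: int = 1, padding: int = 1) -> Tensor:
    """3-D cross-correlation; x: (N, C, D, H, W), w: (O, C, k, k, k), k odd.

    Forward and both gradients are im2col + GEMM: the weight gradient reuses
    the forward's column matrix, and the input gradient is the correlation of
    the zero-stuffed output gradient with the channel-swapped flipped kernel.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, c, d, h, wd = x.shape
    o, c2, k, _, _ = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, weight {c2}")
    p, s = padding, stride
    data, cols = _corr3d(x.data, w.data, s, p, return_cols=True)
    do, ho, wo = data.shape[2:]

    def backward(g):
        if w.requires_grad:
            g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, o)
            w._accumulate((g2.T @ cols).reshape(w.shape))
        if x.requires_grad:
            wt = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
            if s == 1:
                gs = g
            else:  # zero-stuff to undo the stride, with residual right padding
                ext = [(e + 2 * p - k) - s * (q - 1) for e, q in
                       zip((d, h, wd), (do, ho, wo))]
                gs = np.zeros((n, o, s * (do - 1) + 1 + ext[0],
                               s * (ho - 1) + 1 + ext[1],
                               s * (wo - 1) + 1 + ext[2]), dtype=g.dtype)
                gs[:, :, ::s, ::s, ::s][:, :, :do, :ho, :wo] = g
            x._accumulate(_corr3d(gs, wt, 1, k - 1 - p))

    return _make(data, (x, w), backward)


def conv_transpose3d_2x(x, w) -> Tensor:
    """Transposed convolution, kernel 2 stride 2: doubles every spatial axis.

    x: (N, C, D, H, W); w: (C, O, 2, 2, 2). Blocks do not overlap, so the op is
    a channel contraction followed by an interleaving reshape.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, c, d, h, wd = x.shape
    c2, o = w.shape[0], w.shape[1]
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, weight {c2}")
    t = np.tensordot(x.data, w.data, axes=([1], [0]))  # (N,D,H,W,O,2,2,2)
    t = t.transpose(0, 4, 1, 5, 2, 6, 3, 7)  # (N,O,D,2,H,2,W,2)
    data = np.ascontiguousarray(t).reshape(n, o, 2 * d, 2 * h, 2 * wd)

    def backward(g):
        gb = g.reshape(n, o, d, 2, h, 2, wd, 2).transpose(0, 2, 4, 6, 1, 3, 5, 7)
        # gb: (N, D, H, W, O, 2, 2, 2)
        if w.requires_grad:
            gw = np.tensordot(x.data, gb, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
            w._accumulate(gw)
        if x.requires_grad:
            gx = np.tensordot(gb, w.data, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
            x._accumulate(gx.transpose(0, 4, 1, 2, 3))

    return _make(data, (x, w), backward)


def instance_norm(x, gamma=None, beta=None, eps: float = 1e-5) -> Tensor:
    """Normalise each (sample, channel) over the spatial axes of a
    (N, C, D, H, W) tensor, with optional affine parameters shaped
    (1, C, 1, 1, 1). Fused primitive with a hand-derived backward."""
    x = as_tensor(x)
    axes = (2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    centered = x.data - mu
    var = (centered ** 2).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = centered * inv
    if gamma is not None:
        gamma, beta = as_tensor(gamma), as_tensor(beta)
        data = gamma.data * xhat + beta.data
        parents: tuple = (x, gamma, beta)
    else:
        data = xhat
        parents = (x,)

    def backward(g):
        if gamma is not None:
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0,) + axes, keepdims=True))
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0,) + axes, keepdims=True))
            gh = g * gamma.data
        else:
            gh = g
        if x.requires_grad:
            m1 = gh.mean(axis=axes, keepdims=True)
            m2 = (gh * xhat).mean(axis=axes, keepdims=True)
            x._accumulate(inv * (gh - m1 - xhat * m2))

    return _make(data, parents, backward)


def upsample_nearest(x, factor: int) -> Tensor:
    """Nearest-neighbour upsampling of a (N, C, D, H, W) tensor."""
    x = as_tensor(x)
    f = int(factor)
    data = x.data.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)

    def backward(g):
        if x.requires_grad:
            n, c, d, h, w = x.shape
            gr = g.reshape(n, c, d, f, h, f, w, f).sum(axis=(3, 5, 7))
            x._accumulate(gr)

    return _make(data, (x,), backward)
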