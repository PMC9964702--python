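"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the operations the segmentation network
needs: broadcast arithmetic, element-wise nonlinearities, n-dimensional
cross-correlation ("convolution" in the CNN sense) for 2 and 3 spatial
dimensions, 2x2 max-pooling, nearest-neighbour 2x upsampling, stride-2
transposed convolution, channel concatenation, reductions, a numerically
stable channel log-softmax and target-class gathering for the negative
log-likelihood loss.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which walks the recorded graph in reverse topological order.  Every
operation's gradient is validated against central finite differences in
the test suite.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE) if not isinstance(data, np.ndarray) else data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- convenience -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    # -- autodiff ----------------------------------------------------
    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (must be scalar if grad is None)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            node._backward(node.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad and self._backward is None:
            return
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=DTYPE))


def _needs_grad(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None for t in ts)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# broadcast arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def bw(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    if _needs_grad(a, b):
        out._backward = bw
    return out


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data - b.data, parents=(a, b))

    def bw(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(-g, b.shape))

    if _needs_grad(a, b):
        out._backward = bw
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def bw(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    if _needs_grad(a, b):
        out._backward = bw
    return out


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data / b.data, parents=(a, b))

    def bw(g):
        a._accumulate(_unbroadcast(g / b.data, a.shape))
        b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    if _needs_grad(a, b):
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# element-wise functions
# ---------------------------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.maximum(a.data, 0), parents=(a,))

    def bw(g):
        a._accumulate(g * (a.data > 0))

    if _needs_grad(a):
        out._backward = bw
    return out


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, parents=(a,))

    def bw(g):
        a._accumulate(g * s * (1.0 - s))

    if _needs_grad(a):
        out._backward = bw
    return out


def exp(a: Tensor) -> Tensor:
    a = as_tensor(a)
    e = np.exp(a.data)
    out = Tensor(e, parents=(a,))

    def bw(g):
        a._accumulate(g * e)

    if _needs_grad(a):
        out._backward = bw
    return out


def log(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.log(a.data), parents=(a,))

    def bw(g):
        a._accumulate(g / a.data)

    if _needs_grad(a):
        out._backward = bw
    return out


def sqrt(a: Tensor) -> Tensor:
    a = as_tensor(a)
    r = np.sqrt(a.data)
    out = Tensor(r, parents=(a,))

    def bw(g):
        a._accumulate(g * 0.5 / r)

    if _needs_grad(a):
        out._backward = bw
    return out


def square(a: Tensor) -> Tensor:
    return mul(a, a)


def clamp_min(a: Tensor, lo: float) -> Tensor:
    """max(a, lo); gradient passes only where a > lo."""
    a = as_tensor(a)
    out = Tensor(np.maximum(a.data, lo), parents=(a,))

    def bw(g):
        a._accumulate(g * (a.data > lo))

    if _needs_grad(a):
        out._backward = bw
    return out


def clamp(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clip to [lo, hi]; gradient passes only strictly inside the interval."""
    a = as_tensor(a)
    out = Tensor(np.clip(a.data, lo, hi), parents=(a,))

    def bw(g):
        a._accumulate(g * ((a.data > lo) & (a.data < hi)))

    if _needs_grad(a):
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def bw(g):
        a._accumulate(g.reshape(a.shape))

    if _needs_grad(a):
        out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]

    def bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            t._accumulate(g[tuple(sl)])
            start += s

    if _needs_grad(*tensors):
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def bw(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).astype(a.data.dtype))
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.shape).astype(a.data.dtype))

    if _needs_grad(a):
        out._backward = bw
    return out


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def amax(a: Tensor, axis: int) -> Tensor:
    """Maximum over a single axis; ties break toward the first index."""
    a = as_tensor(a)
    idx = np.argmax(a.data, axis=axis)
    out = Tensor(np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis).squeeze(axis),
                 parents=(a,))

    def bw(g):
        full = np.zeros_like(a.data)
        np.put_along_axis(full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis)
        a._accumulate(full)

    if _needs_grad(a):
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# n-dimensional cross-correlation
# ---------------------------------------------------------------------------

def _channels_last(x: np.ndarray, pad) -> np.ndarray:
    """Pad spatially and move channels to the trailing axis (contiguous)."""
    if any(pad):
        x = np.pad(x, [(0, 0), (0, 0)] + [(p, p) for p in pad])
    return np.ascontiguousarray(np.moveaxis(x, 1, -1))


def _offset_slices(kernel, out_spatial, stride):
    """One spatial slice tuple per kernel offset (im2col without the copy)."""
    from itertools import product

    for offs in product(*[range(k) for k in kernel]):
        yield offs, tuple(slice(o, o + (osz - 1) * s + 1, s)
                          for o, osz, s in zip(offs, out_spatial, stride))


def _out_spatial(in_spatial, kernel, stride, pad):
    return tuple((i + 2 * p - k) // s + 1
                 for i, k, s, p in zip(in_spatial, kernel, stride, pad))


def _convnd_raw(x: np.ndarray, w: np.ndarray, stride, pad) -> np.ndarray:
    """Cross-correlate x (N, Cin, *S) with w (Cout, Cin, *K).

    Computed as one GEMM per kernel offset on a channels-last copy,
    which is much cheaper than materializing the full im2col tensor.
    """
    nd = w.ndim - 2
    co, cin = w.shape[:2]
    out_sp = _out_spatial(x.shape[2:], w.shape[2:], stride, pad)
    xl = _channels_last(x, pad)
    out = np.zeros((x.shape[0],) + out_sp + (co,), dtype=x.dtype)
    out_flat = out.reshape(-1, co)
    for offs, sl in _offset_slices(w.shape[2:], out_sp, stride):
        xs = xl[(slice(None),) + sl + (slice(None),)]
        xs = np.ascontiguousarray(xs).reshape(-1, cin)
        wk = w[(slice(None), slice(None)) + offs]  # (Cout, Cin)
        out_flat += xs @ wk.T
    return np.ascontiguousarray(np.moveaxis(out, -1, 1))


def convnd(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, pad=0) -> Tensor:
    """Cross-correlation with 2 or 3 spatial dims, optional channel bias."""
    x, w = as_tensor(x), as_tensor(w)
    nd = w.ndim - 2
    if isinstance(stride, int):
        stride = (stride,) * nd
    if isinstance(pad, int):
        pad = (pad,) * nd
    co, cin = w.shape[:2]
    out_sp = _out_spatial(x.shape[2:], w.shape[2:], stride, pad)
    xl = _channels_last(x.data, pad)
    y = np.zeros((x.shape[0],) + out_sp + (co,), dtype=x.data.dtype)
    y_flat = y.reshape(-1, co)
    for offs, sl in _offset_slices(w.shape[2:], out_sp, stride):
        xs = np.ascontiguousarray(xl[(slice(None),) + sl + (slice(None),)])
        y_flat += xs.reshape(-1, cin) @ w.data[(slice(None), slice(None)) + offs].T
    y = np.moveaxis(y, -1, 1)
    if b is not None:
        b = as_tensor(b)
        y = y + b.data.reshape((1, -1) + (1,) * nd)
    y = np.ascontiguousarray(y)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def bw(g):
        go = np.ascontiguousarray(np.moveaxis(g, 1, -1))
        go_flat = go.reshape(-1, co)
        gw = np.zeros_like(w.data)
        gxl = np.zeros_like(xl)
        for offs, sl in _offset_slices(w.shape[2:], out_sp, stride):
            idx = (slice(None),) + sl + (slice(None),)
            xs = np.ascontiguousarray(xl[idx]).reshape(-1, cin)
            wk = w.data[(slice(None), slice(None)) + offs]
            gw[(slice(None), slice(None)) + offs] = go_flat.T @ xs
            gxl[idx] += (go_flat @ wk).reshape(gxl[idx].shape)
        w._accumulate(gw)
        gx = np.moveaxis(gxl, -1, 1)
        if any(pad):
            core = (slice(None), slice(None)) + tuple(
                slice(p, p + s) for p, s in zip(pad, x.shape[2:]))
            gx = gx[core]
        x._accumulate(np.ascontiguousarray(gx))
        if b is not None:
            b._accumulate(g.sum(axis=(0,) + tuple(range(2, 2 + nd))))

    if _needs_grad(*parents):
        out._backward = bw
    return out


def conv_transpose2x(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2: exact spatial doubling.

    ``w`` has shape (Cin, Cout, 2, 2).
    """
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.shape
    co = w.shape[1]
    y = np.einsum("nchw,cokl->nohkwl", x.data, w.data, optimize=True)
    y = y.reshape(n, co, 2 * h, 2 * wd)
    if b is not None:
        b = as_tensor(b)
        y = y + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def bw(g):
        gr = g.reshape(n, co, h, 2, wd, 2)
        x._accumulate(np.einsum("nohkwl,cokl->nchw", gr, w.data, optimize=True))
        w._accumulate(np.einsum("nohkwl,nchw->cokl", gr, x.data, optimize=True))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    if _needs_grad(*parents):
        out._backward = bw
    return out


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max-pooling over the trailing two axes (extents must be even)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2d requires even extents, got {(h, w)}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = np.argmax(flat, axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], parents=(x,))

    def bw(g):
        gf = np.zeros_like(flat)
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        gx = gf.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(gx)

    if _needs_grad(x):
        out._backward = bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of the trailing two axes."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), parents=(x,))

    def bw(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    if _needs_grad(x):
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# classification head helpers
# ---------------------------------------------------------------------------

def log_softmax_channel(x: Tensor) -> Tensor:
    """Numerically stable log-softmax over axis 1."""
    x = as_tensor(x)
    m = x.data.max(axis=1, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    ls = z - lse
    out = Tensor(ls, parents=(x,))

    def bw(g):
        sm = np.exp(ls)
        x._accumulate(g - sm * g.sum(axis=1, keepdims=True))

    if _needs_grad(x):
        out._backward = bw
    return out


def softmax_channel(x: Tensor) -> Tensor:
    return exp(log_softmax_channel(x))


def take_channel(probs: Tensor, idx: np.ndarray) -> Tensor:
    """Gather probs[n, idx[n, h, w], h, w] -> (N, H, W)."""
    probs = as_tensor(probs)
    idx = np.asarray(idx, dtype=np.int64)
    picked = np.take_along_axis(probs.data, idx[:, None], axis=1)[:, 0]
    out = Tensor(picked, parents=(probs,))

    def bw(g):
        gp = np.zeros_like(probs.data)
        np.put_along_axis(gp, idx[:, None], g[:, None], axis=1)
        probs._accumulate(gp)

    if _needs_grad(probs):
        out._backward = bw
    return out
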