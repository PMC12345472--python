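"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the operator set needed by the face-identification
models in this package: broadcast arithmetic, matrix products, 2-D convolution
(via im2col and a transposed-convolution backward), pooling, batch
normalization and the usual pointwise nonlinearities.  Tensors are float32 by
default; gradients are accumulated in the same dtype.

Graph recording can be suspended with :func:`no_grad` for inference paths.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph recording."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this tensor."""
        if grad is None:
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# -- arithmetic ---------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(data, (a, b), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.data.shape
    data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(old))

    return _make(data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                t._accumulate(g[tuple(sl)])
            start += s

    return _make(data, tuple(tensors), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


# -- pointwise ----------------------------------------------------------

def relu(a) -> Tensor:
    a = as_tensor(a)
    data = np.maximum(a.data, 0.0)

    def backward(g):
        a._accumulate(g * (a.data > 0))

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    with np.errstate(over="ignore"):
        data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    data = np.sqrt(a.data)

    def backward(g):
        a._accumulate(g * 0.5 / data)

    return _make(data, (a,), backward)


def square(a) -> Tensor:
    return mul(a, a)


# -- convolution and pooling -------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (n, c, oh, ow, kh, kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    return cols, oh, ow


def conv2d(x, w, b=None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation; ``x``: (N,C,H,W), ``w``: (O,C,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wid = x.data.shape
    o, _, kh, kw = w.data.shape
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(o, -1)
    out = (cols @ wmat.T).reshape(n, oh, ow, o).transpose(0, 3, 1, 2)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, o)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accumulate((gmat.T @ cols).reshape(w.data.shape))
        if x.requires_grad:
            # transposed convolution: dilate gradient by stride, pad, flip kernel
            if stride > 1:
                gd = np.zeros((n, o, (oh - 1) * stride + 1, (ow - 1) * stride + 1),
                              dtype=g.dtype)
                gd[:, :, ::stride, ::stride] = g
            else:
                gd = g
            # ensure reconstruction covers the padded input extent
            hpad, wpad = h + 2 * pad, wid + 2 * pad
            need_h = hpad - kh + 1
            need_w = wpad - kw + 1
            eh = need_h - gd.shape[2]
            ew = need_w - gd.shape[3]
            gd = np.pad(gd, ((0, 0), (0, 0), (kh - 1, kh - 1 + eh), (kw - 1, kw - 1 + ew)))
            wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,O,kh,kw)
            cols_g, gh, gw = _im2col(gd, kh, kw, 1, 0)
            dx = (cols_g @ wflip.reshape(c, -1).T).reshape(n, gh, gw, c).transpose(0, 3, 1, 2)
            if pad:
                dx = dx[:, :, pad:pad + h, pad:pad + wid]
            x._accumulate(dx)

    return _make(out, parents, backward)


def max_pool2d(x, k: int, stride: int, pad: int = 0) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=-np.inf) if pad else x.data
    hp, wp = xp.shape[2], xp.shape[3]
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride].reshape(n, c, oh, ow, k * k)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
        ki, kj = np.unravel_index(idx, (k, k))
        oi = np.arange(oh)[None, None, :, None] * stride
        oj = np.arange(ow)[None, None, None, :] * stride
        rows = (oi + ki).ravel()
        cols_ = (oj + kj).ravel()
        ni = np.repeat(np.arange(n), c * oh * ow)
        ci = np.tile(np.repeat(np.arange(c), oh * ow), n)
        np.add.at(dxp, (ni, ci, rows, cols_), g.ravel())
        if pad:
            dxp = dxp[:, :, pad:pad + h, pad:pad + w]
        x._accumulate(dxp)

    return _make(np.ascontiguousarray(out), (x,), backward)


def global_avg_pool(x) -> Tensor:
    """(N,C,H,W) -> (N,C)."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    data = x.data.mean(axis=(2, 3))

    def backward(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    return _make(data, (x,), backward)


def global_max_pool(x) -> Tensor:
    """(N,C,H,W) -> (N,C)."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=2)
    data = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        df = np.zeros_like(flat)
        np.put_along_axis(df, idx[:, :, None], g[:, :, None], axis=2)
        x._accumulate(df.reshape(x.data.shape))

    return _make(data, (x,), backward)


def channel_mean_map(x) -> Tensor:
    """(N,C,H,W) -> (N,1,H,W) mean over channels."""
    x = as_tensor(x)
    c = x.data.shape[1]
    data = x.data.mean(axis=1, keepdims=True)

    def backward(g):
        x._accumulate(np.broadcast_to(g / c, x.data.shape))

    return _make(data, (x,), backward)


def channel_max_map(x) -> Tensor:
    """(N,C,H,W) -> (N,1,H,W) max over channels."""
    x = as_tensor(x)
    idx = x.data.argmax(axis=1, keepdims=True)
    data = np.take_along_axis(x.data, idx, axis=1)

    def backward(g):
        dx = np.zeros_like(x.data)
        np.put_along_axis(dx, idx, g, axis=1)
        x._accumulate(dx)

    return _make(data, (x,), backward)


def conv1d_channels(x, kernel) -> Tensor:
    """Same-padded 1-D convolution along the channel axis; ``x``: (N,C), kernel (k,)."""
    x, kernel = as_tensor(x), as_tensor(kernel)
    k = kernel.data.shape[0]
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (N, C, k)
    data = win @ kernel.data

    def backward(g):
        if kernel.requires_grad:
            kernel._accumulate(np.einsum("nck,nc->k", win, g))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (pad, pad)))
            gwin = np.lib.stride_tricks.sliding_window_view(gp, k, axis=1)
            x._accumulate(gwin @ kernel.data[::-1].copy())

    return _make(data, (x, kernel), backward)


def batch_norm(x, gamma, beta, running_mean, running_var, training: bool,
               momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N,) or (N,H,W) per channel.

    ``x`` is (N,C) or (N,C,H,W); ``gamma``/``beta`` are (C,).  Running
    statistics (plain ndarrays) are updated in place during training.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (0,) if x.data.ndim == 2 else (0, 2, 3)
    shape = (1, -1) if x.data.ndim == 2 else (1, -1, 1, 1)
    if training:
        mu = x.data.mean(axis=axes)
        # single-pass variance via E[x^2] - mu^2; activations are O(1) so the
        # cancellation error is negligible at float32
        var = np.maximum((x.data * x.data).mean(axis=axes) - mu * mu, 0.0)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        n_el = x.data.size // x.data.shape[1]
        unbiased = var * (n_el / max(n_el - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mu, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    scale = (gamma.data * invstd).astype(x.data.dtype)
    shift = (beta.data - mu * scale).astype(x.data.dtype)
    out = x.data * scale.reshape(shape) + shift.reshape(shape)

    def backward(g):
        gsum = g.sum(axis=axes)
        gx = (g * x.data).sum(axis=axes)
        if beta.requires_grad:
            beta._accumulate(gsum)
        if gamma.requires_grad:
            # sum g * xhat expressed through raw-x channel sums
            gamma._accumulate((gx - mu * gsum) * invstd)
        if x.requires_grad:
            if training:
                n_el = x.data.size // x.data.shape[1]
                t1 = gamma.data * invstd * gsum
                t2 = (gamma.data * invstd) * (gx - mu * gsum) * invstd
                c1 = (gamma.data * invstd).astype(g.dtype)
                c2 = (-t2 * invstd / n_el).astype(g.dtype)
                c3 = ((-t1 + t2 * invstd * mu) / n_el).astype(g.dtype)
                dx = g * c1.reshape(shape) + x.data * c2.reshape(shape) \
                    + c3.reshape(shape)
            else:
                dx = g * (gamma.data * invstd).reshape(shape).astype(g.dtype)
            x._accumulate(dx)

    return _make(out, (x, gamma, beta), backward)


def bilinear_resize(x: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Plain-numpy bilinear resize of a 2-D map (no gradient)."""
    h, w = x.shape
    if h == out_h and w == out_w:
        return x.copy()
    yi = np.linspace(0, h - 1, out_h)
    xi = np.linspace(0, w - 1, out_w)
    y0 = np.floor(yi).astype(int)
    x0 = np.floor(xi).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (yi - y0)[:, None]
    wx = (xi - x0)[None, :]
    return ((1 - wy) * (1 - wx) * x[np.ix_(y0, x0)] + (1 - wy) * wx * x[np.ix_(y0, x1)]
            + wy * (1 - wx) * x[np.ix_(y1, x0)] + wy * wx * x[np.ix_(y1, x1)])
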