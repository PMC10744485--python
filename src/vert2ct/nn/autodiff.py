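"""Minimal reverse-mode automatic differentiation on numpy arrays.

The reconstruction network is small (single-sample batches, desk-scale
volumes), so the engine favours clarity over generality: a ``Tensor`` wraps
one ndarray, ops build a tape, and :meth:`Tensor.backward` walks it in
reverse topological order.  Convolutions are the only non-trivial kernels;
they are implemented with ``sliding_window_view`` + ``einsum`` and chunked
along the leading spatial axis so peak memory stays bounded at 128-cube
feature maps.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "square",
    "absolute",
    "mean",
    "summation",
    "relu",
    "sigmoid",
    "power",
    "concat",
    "reshape",
    "transpose",
    "flip",
    "rot90",
    "repeat_new_axis",
    "zero_stuff",
    "crop",
    "conv",
    "instance_norm",
]


class Tensor:
    """A node in the autodiff graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                order.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen and p.requires_grad:
                        stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # operator sugar -------------------------------------------------
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

    def __neg__(self):
        return mul(self, -1.0)

    def __float__(self):
        return float(self.data)

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    out._backward = backward
    return out


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data - b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.shape))

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    out._backward = backward
    return out


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data**exponent, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * exponent * a.data ** (exponent - 1.0))

    out._backward = backward
    return out


def square(a) -> Tensor:
    return power(a, 2.0)


def absolute(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.abs(a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * np.sign(a.data))

    out._backward = backward
    return out


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.mean(axis=axis, keepdims=keepdims), parents=(a,))
    count = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in np.atleast_1d(axis)]
    )

    def backward(g):
        if not a.requires_grad:
            return
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, tuple(np.atleast_1d(axis)))
        a._accumulate(np.broadcast_to(g, a.shape) / count)

    out._backward = backward
    return out


def summation(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def backward(g):
        if not a.requires_grad:
            return
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, tuple(np.atleast_1d(axis)))
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    out._backward = backward
    return out


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.maximum(a.data, 0.0), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > 0))

    out._backward = backward
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    out._backward = backward
    return out


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward = backward
    return out


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    out._backward = backward
    return out


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.transpose(axes), parents=(a,))
    inverse = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inverse))

    out._backward = backward
    return out


def flip(a, axes) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.flip(a.data, axes), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.flip(g, axes))

    out._backward = backward
    return out


def rot90(a, k=1, axes=(1, 2)) -> Tensor:
    """Exact lattice rotation by k*90 degrees in the given axis plane."""
    a = as_tensor(a)
    out = Tensor(np.rot90(a.data, k=k, axes=axes), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.rot90(g, k=-k, axes=axes))

    out._backward = backward
    return out


def repeat_new_axis(a, n: int, axis: int) -> Tensor:
    """Insert a new axis of length ``n`` by repetition (2D -> pseudo-3D maps)."""
    a = as_tensor(a)
    out = Tensor(
        np.repeat(np.expand_dims(a.data, axis), n, axis=axis), parents=(a,)
    )

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.sum(axis=axis))

    out._backward = backward
    return out


def zero_stuff(a, stride: int, spatial_start: int = 1) -> Tensor:
    """Insert ``stride - 1`` zeros between elements on every spatial axis.

    Used to express transposed convolution through the plain convolution
    kernel.  Axes before ``spatial_start`` (channels) are untouched.
    """
    a = as_tensor(a)
    if stride == 1:
        return a
    shape = list(a.shape)
    for ax in range(spatial_start, len(shape)):
        shape[ax] = (shape[ax] - 1) * stride + 1
    stuffed = np.zeros(shape, dtype=a.data.dtype)
    idx = tuple(
        slice(None) if ax < spatial_start else slice(None, None, stride)
        for ax in range(len(shape))
    )
    stuffed[idx] = a.data
    out = Tensor(stuffed, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[idx])

    out._backward = backward
    return out


def crop(a, slices) -> Tensor:
    a = as_tensor(a)
    slices = tuple(slices)
    out = Tensor(a.data[slices], parents=(a,))

    def backward(g):
        if a.requires_grad:
            full = np.zeros(a.shape, dtype=g.dtype)
            full[slices] = g
            a._accumulate(full)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

_EINSUM_FWD = {
    2: ("chwij,ocij->ohw", "chwij,ohw->ocij"),
    3: ("cdhwijk,ocijk->odhw", "cdhwijk,odhw->ocijk"),
}

# chunk size chosen so the materialised einsum operand stays ~tens of MB
_CHUNK_ELEMS = 4_000_000


def _conv_forward_raw(x, w, stride, pad):
    nd = x.ndim - 1
    k = w.shape[2:]
    if pad:
        x = np.pad(x, ((0, 0),) + tuple((p, p) for p in pad))
    win = sliding_window_view(x, k, axis=tuple(range(1, nd + 1)))
    sl = (slice(None),) + tuple(slice(None, None, s) for s in stride)
    win = win[sl]
    spec, _ = _EINSUM_FWD[nd]
    out_spatial = win.shape[1 : 1 + nd]
    cin_k = x.shape[0] * int(np.prod(k))
    chunk = max(1, _CHUNK_ELEMS // max(1, int(np.prod(out_spatial[1:])) * cin_k))
    parts = []
    for lo in range(0, out_spatial[0], chunk):
        parts.append(
            np.einsum(spec, win[:, lo : lo + chunk], w, optimize=True)
        )
    return np.concatenate(parts, axis=1) if len(parts) > 1 else parts[0]


def _conv_weight_grad_raw(x, dy, w_shape, stride, pad):
    nd = x.ndim - 1
    k = w_shape[2:]
    if pad:
        x = np.pad(x, ((0, 0),) + tuple((p, p) for p in pad))
    win = sliding_window_view(x, k, axis=tuple(range(1, nd + 1)))
    sl = (slice(None),) + tuple(slice(None, None, s) for s in stride)
    win = win[sl]
    _, spec = _EINSUM_FWD[nd]
    out_spatial = win.shape[1 : 1 + nd]
    cin_k = x.shape[0] * int(np.prod(k))
    chunk = max(1, _CHUNK_ELEMS // max(1, int(np.prod(out_spatial[1:])) * cin_k))
    dw = np.zeros(w_shape, dtype=x.dtype)
    for lo in range(0, out_spatial[0], chunk):
        dw += np.einsum(spec, win[:, lo : lo + chunk], dy[:, lo : lo + chunk], optimize=True)
    return dw


def _conv_input_grad_raw(dy, w, x_shape, stride, pad):
    # full correlation of the zero-stuffed upstream grad with flipped kernels
    nd = dy.ndim - 1
    k = w.shape[2:]
    shape = list(dy.shape)
    for ax in range(1, nd + 1):
        shape[ax] = (shape[ax] - 1) * stride[ax - 1] + 1
    stuffed = np.zeros(shape, dtype=dy.dtype)
    stuffed[
        (slice(None),) + tuple(slice(None, None, s) for s in stride)
    ] = dy
    w_t = np.flip(w, axis=tuple(range(2, 2 + nd))).swapaxes(0, 1)
    # full correlation aligns output index t with input index i when the
    # left pad is k-1-p; the right pad absorbs inputs past the last window
    pads = [(0, 0)]
    for ax in range(nd):
        left = k[ax] - 1 - pad[ax]
        reach = stuffed.shape[1 + ax] + k[ax] - 2 * pad[ax] - 1
        extra = x_shape[1 + ax] - reach
        pads.append((left, left + max(extra, 0)))
    dx = _conv_forward_raw(np.pad(stuffed, pads), w_t, (1,) * nd, (0,) * nd)
    return dx[(slice(None),) + tuple(slice(0, s) for s in x_shape[1:])]


def conv(x, w, bias=None, stride=1, pad=0) -> Tensor:
    """N-d cross-correlation, channels-first, no batch axis.

    ``x``: (C_in, *spatial); ``w``: (C_out, C_in, *kernel); output
    (C_out, *out_spatial) with out = (S + 2p - k) // stride + 1.
    """
    x, w = as_tensor(x), as_tensor(w)
    nd = x.ndim - 1
    if nd not in (2, 3):
        raise ValueError("conv supports 2D and 3D inputs")
    stride = (stride,) * nd if np.isscalar(stride) else tuple(stride)
    pad = (pad,) * nd if np.isscalar(pad) else tuple(pad)
    y = _conv_forward_raw(x.data, w.data, stride, pad)
    parents = (x, w) if bias is None else (x, w, as_tensor(bias))
    if bias is not None:
        b = parents[2]
        y = y + b.data.reshape((-1,) + (1,) * nd)
    out = Tensor(y, parents=parents)

    def backward(g):
        if x.requires_grad:
            x._accumulate(_conv_input_grad_raw(g, w.data, x.shape, stride, pad))
        if w.requires_grad:
            w._accumulate(_conv_weight_grad_raw(x.data, g, w.shape, stride, pad))
        if bias is not None and parents[2].requires_grad:
            parents[2]._accumulate(g.sum(axis=tuple(range(1, nd + 1))))

    out._backward = backward
    return out


def instance_norm(x, eps: float = 1e-5) -> Tensor:
    """Per-channel normalisation over spatial axes (no affine parameters)."""
    x = as_tensor(x)
    axes = tuple(range(1, x.ndim))
    mu = mean(x, axis=axes, keepdims=True)
    centred = sub(x, mu)
    var = mean(square(centred), axis=axes, keepdims=True)
    inv = power(add(var, eps), -0.5)
    return mul(centred, inv)
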