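"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations needed by the segmentation networks are implemented.
Tensors wrap ``numpy.ndarray`` data; every differentiable operation records
a backward closure so :meth:`Tensor.backward` can accumulate gradients by
reverse topological traversal.  Dtype follows the operands (tests use
float64 for numerical gradient checks, networks run in float32).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import special as _special

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "no_grad",
    "is_grad_enabled",
    "concatenate",
    "matmul",
    "exp",
    "log",
    "erf",
    "sigmoid",
    "tanh",
    "relu",
    "gelu",
    "softmax",
    "layer_norm",
    "conv2d",
    "depthwise_conv2d",
    "max_pool2d",
    "avg_pool2d",
    "bilinear_resize",
    "pad_circular_1d",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- core properties -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    # -- backward ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, self.dtype)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, self.dtype)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, self.dtype)
        out_data = self.data / other.data

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / (other.data**2), other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other, self.dtype) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.data.shape

        def backward(g):
            full = np.zeros(shape, dtype=g.dtype)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(a % len(shape) for a in ax)
                g = np.expand_dims(g, tuple(sorted(ax)))
            self._accum(np.broadcast_to(g, shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


class Parameter(Tensor):
    """A tensor registered as trainable state of a module."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None and arr.dtype != dtype and np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    elif dtype is not None and arr.dtype.kind in "iub":
        arr = arr.astype(dtype)
    return Tensor(arr)


# -- free functions ------------------------------------------------------------


def matmul(a: Tensor, b) -> Tensor:
    b = as_tensor(b, a.dtype)
    out_data = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a._accum(_unbroadcast(ga, a.data.shape))
        b._accum(_unbroadcast(gb, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._make(out_data, tuple(tensors), backward)


def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def backward(g):
        x._accum(g * out_data)

    return Tensor._make(out_data, (x,), backward)


def log(x: Tensor) -> Tensor:
    def backward(g):
        x._accum(g / x.data)

    return Tensor._make(np.log(x.data), (x,), backward)


def erf(x: Tensor) -> Tensor:
    out_data = _special.erf(x.data)
    coef = 2.0 / np.sqrt(np.pi)

    def backward(g):
        x._accum(g * coef * np.exp(-x.data**2))

    return Tensor._make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = _special.expit(x.data)

    def backward(g):
        x._accum(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(g):
        x._accum(g * (1.0 - out_data**2))

    return Tensor._make(out_data, (x,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accum(g * mask)

    return Tensor._make(np.where(mask, x.data, 0), (x,), backward)


def gelu(x: Tensor) -> Tensor:
    # exact (erf) form
    return x * (erf(x * float(1.0 / np.sqrt(2.0))) + 1.0) * 0.5


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - x.data.max(axis=axis, keepdims=True)
    e = exp(shift)
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, axis: int = -1, eps: float = 1e-5) -> Tensor:
    """Non-affine layer normalization over ``axis``."""
    mu = x.mean(axis=axis, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=axis, keepdims=True)
    return centered * ((var + eps) ** -0.5)


# -- convolution and pooling ---------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int, oh: int, ow: int):
    b, c = xp.shape[:2]
    sb, sc, sh, sw = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, c, kh, kw, oh, ow),
        strides=(sb, sc, sh * dilation, sw * dilation, sh * stride, sw * stride),
        writeable=False,
    )
    return np.ascontiguousarray(cols).reshape(b, c * kh * kw, oh * ow)


def conv2d(x: Tensor, w: Tensor, bias: Tensor | None = None, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2D cross-correlation; x (B,C,H,W), w (OC,C,KH,KW), bias (OC,)."""
    b, c, h, wd = x.data.shape
    oc, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {ci}")
    eff_kh = (kh - 1) * dilation + 1
    eff_kw = (kw - 1) * dilation + 1
    oh = (h + 2 * padding - eff_kh) // stride + 1
    ow = (wd + 2 * padding - eff_kw) // stride + 1
    if oh < 1 or ow < 1:
        raise ValueError("conv2d output extent would be empty")
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    cols = _im2col(xp, kh, kw, stride, dilation, oh, ow)  # (B, C*KH*KW, OH*OW)
    wmat = w.data.reshape(oc, c * kh * kw)
    out = np.matmul(wmat, cols)  # (B, OC, OH*OW)
    if bias is not None:
        out = out + bias.data.reshape(1, oc, 1)
    out = out.reshape(b, oc, oh, ow)
    parents = (x, w) if bias is None else (x, w, bias)

    def backward(g):
        gmat = g.reshape(b, oc, oh * ow)
        if bias is not None:
            bias._accum(gmat.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            dcols = np.matmul(wmat.T, gmat)  # (B, C*KH*KW, OH*OW)
            dcols = dcols.reshape(b, c, kh, kw, oh, ow)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                hi = i * dilation
                for j in range(kw):
                    wj = j * dilation
                    gxp[:, :, hi:hi + oh * stride:stride, wj:wj + ow * stride:stride] += dcols[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    return Tensor._make(out, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, bias: Tensor | None = None,
                     padding: int = 0, dilation: int = 1) -> Tensor:
    """Per-channel 2D convolution; x (B,C,H,W), w (C,KH,KW), bias (C,)."""
    b, c, h, wd = x.data.shape
    cw, kh, kw = w.data.shape
    if cw != c:
        raise ValueError("depthwise_conv2d channel mismatch")
    oh = h + 2 * padding - (kh - 1) * dilation
    ow = wd + 2 * padding - (kw - 1) * dilation
    if oh < 1 or ow < 1:
        raise ValueError("depthwise_conv2d output extent would be empty")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    out = np.zeros((b, c, oh, ow), dtype=x.data.dtype)
    for i in range(kh):
        hi = i * dilation
        for j in range(kw):
            wj = j * dilation
            out += w.data[None, :, i, j, None, None] * xp[:, :, hi:hi + oh, wj:wj + ow]
    if bias is not None:
        out += bias.data[None, :, None, None]
    parents = (x, w) if bias is None else (x, w, bias)

    def backward(g):
        if bias is not None:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i in range(kh):
                hi = i * dilation
                for j in range(kw):
                    wj = j * dilation
                    gw[:, i, j] = (g * xp[:, :, hi:hi + oh, wj:wj + ow]).sum(axis=(0, 2, 3))
            w._accum(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                hi = i * dilation
                for j in range(kw):
                    wj = j * dilation
                    gxp[:, :, hi:hi + oh, wj:wj + ow] += g * w.data[None, :, i, j, None, None]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int = 2) -> Tensor:
    b, c, h, w = x.data.shape
    if h % kernel or w % kernel:
        raise ValueError("max_pool2d requires extents divisible by the kernel")
    oh, ow = h // kernel, w // kernel
    blocks = x.data.reshape(b, c, oh, kernel, ow, kernel).transpose(0, 1, 2, 4, 3, 5)
    blocks = blocks.reshape(b, c, oh, ow, kernel * kernel)
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gb = np.zeros((b, c, oh, ow, kernel * kernel), dtype=g.dtype)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gb = gb.reshape(b, c, oh, ow, kernel, kernel).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gb.reshape(b, c, h, w))

    return Tensor._make(out, (x,), backward)


def avg_pool2d(x: Tensor, kernel: int) -> Tensor:
    b, c, h, w = x.shape
    if h % kernel or w % kernel:
        raise ValueError("avg_pool2d requires extents divisible by the kernel")
    oh, ow = h // kernel, w // kernel
    return x.reshape(b, c, oh, kernel, ow, kernel).mean(axis=(3, 5))


def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Row-stochastic 1D linear-interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        m[i, lo] += 1.0 - frac
        m[i, hi] += frac
    return m


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of (B,C,H,W) via constant interpolation matrices."""
    b, c, h, w = x.shape
    oh, ow = out_hw
    if (oh, ow) == (h, w):
        return x
    mh = Tensor(_interp_matrix(oh, h, x.dtype))
    mw = Tensor(_interp_matrix(ow, w, x.dtype))
    return matmul(matmul(mh, x), mw.swapaxes(0, 1))


def pad_circular_1d(x: Tensor, pad: int, axis: int = -1) -> Tensor:
    """Circular (wrap) padding along one axis, built from slices + concat."""
    if pad == 0:
        return x
    n = x.shape[axis]
    if pad > n:
        raise ValueError("circular pad wider than the axis")
    idx_head = [slice(None)] * x.ndim
    idx_tail = [slice(None)] * x.ndim
    idx_head[axis] = slice(n - pad, n)
    idx_tail[axis] = slice(0, pad)
    return concatenate([x[tuple(idx_head)], x, x[tuple(idx_tail)]], axis=axis)
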