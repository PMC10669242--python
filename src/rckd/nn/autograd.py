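"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every operation builds a node holding
references to its inputs and a closure that accumulates gradients into them.
Arrays keep whatever float dtype they come in with, so loss formulas evaluated
on float64 inputs retain float64 precision.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "Parameter", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad=False, _prev=(), _backward=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = _backward
        self._prev = _prev if self.requires_grad else ()
        self.name = None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def numpy(self):
        return self.data

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    # -- graph machinery ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      _prev=tuple(p for p in parents if p.requires_grad),
                      _backward=backward if req else None)

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=grad.dtype if grad.dtype.kind == "f" else np.float64)
        self.grad = self.grad + grad

    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            if self.size != 1:
                raise RuntimeError("backward() without gradient only for scalars")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p):
        assert np.isscalar(p)
        out_data = self.data ** p

        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod([self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        arg = np.expand_dims(self.data.argmax(axis=axis), axis)

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            gx = np.zeros_like(self.data, dtype=g.dtype)
            np.put_along_axis(gx, arg, g, axis)
            self._accumulate(gx)

        return Tensor._make(out_data, (self,), backward)

    # -- shaping ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        src = self.shape

        def backward(g):
            self._accumulate(g.reshape(src))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            gx = np.zeros_like(self.data, dtype=g.dtype)
            np.add.at(gx, idx, g)
            self._accumulate(gx)

        return Tensor._make(out_data, (self,), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out_data = x * cdf
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)

        def backward(g):
            self._accumulate(g * (cdf + x * pdf))

        return Tensor._make(out_data, (self,), backward)

    def clamp(self, lo, hi):
        """Clamp values with a straight-through gradient.

        Passing the gradient unchanged (rather than zeroing it outside the
        interior) keeps saturated probabilities trainable when the clamp
        guards a log() inside a loss.
        """
        out_data = np.clip(self.data, lo, hi)

        def backward(g):
            self._accumulate(np.asarray(g))

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accumulate(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward)


class Parameter(Tensor):
    """A trainable tensor (float64: full-precision softmax/log gradients)."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


# -- multi-input / structured ops --------------------------------------------

def concat(tensors, axis=0):
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def pad2d(x: Tensor, pad: int, mode: str = "zeros") -> Tensor:
    """Pad the two trailing (spatial) axes of an NCHW tensor."""
    if pad == 0:
        return x
    if mode == "zeros":
        out_data = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))

        def backward(g):
            x._accumulate(g[..., pad:-pad, pad:-pad])

        return Tensor._make(out_data, (x,), backward)
    if mode == "edge":
        H, W = x.shape[-2:]
        ih = np.clip(np.arange(-pad, H + pad), 0, H - 1)
        iw = np.clip(np.arange(-pad, W + pad), 0, W - 1)
        out_data = x.data[..., ih[:, None], iw[None, :]]

        def backward(g):
            gx = np.zeros_like(x.data, dtype=g.dtype)
            np.add.at(gx, (..., ih[:, None], iw[None, :]), g)
            x._accumulate(gx)

        return Tensor._make(out_data, (x,), backward)
    raise ValueError(f"unknown pad mode {mode!r}")


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    N, C, H, W = x.shape
    Ho = (H - kh) // sh + 1
    Wo = (W - kw) // sw + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(N, C, kh, kw, Ho, Wo), strides=(s0, s1, s2, s3, s2 * sh, s3 * sw),
        writeable=False)
    return windows, Ho, Wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0, groups: int = 1, pad_mode: str = "zeros") -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel/stride."""
    xp = pad2d(x, padding, pad_mode)
    Co, Cg, kh, kw = w.shape
    N, C, H, W = xp.shape
    if C != Cg * groups:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cg * groups}")
    windows, Ho, Wo = _im2col(xp.data, kh, kw, stride, stride)
    cols = windows.reshape(N, groups, Cg * kh * kw, Ho * Wo)
    wmat = w.data.reshape(groups, Co // groups, Cg * kh * kw)
    out = np.matmul(wmat[None], cols)                    # (N, g, Co/g, L)
    out_data = out.reshape(N, Co, Ho, Wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Co, 1, 1)

    parents = (xp, w) + ((b,) if b is not None else ())

    def backward(g):
        gmat = g.reshape(N, groups, Co // groups, Ho * Wo)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.matmul(gmat, np.swapaxes(cols, -1, -2)).sum(axis=0)  # (g, Co/g, CgKK)
            w._accumulate(gw.reshape(w.shape))
        if xp.requires_grad:
            gcols = np.matmul(np.swapaxes(wmat, -1, -2)[None], gmat)     # (N, g, CgKK, L)
            gcols = gcols.reshape(N, C, kh, kw, Ho, Wo)
            gx = np.zeros((N, C, H, W), dtype=gcols.dtype)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += gcols[:, :, i, j]
            xp._accumulate(gx)

    return Tensor._make(out_data, parents, backward)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    xp = pad2d(x, padding, "zeros") if padding else x
    windows, Ho, Wo = _im2col(xp.data, kernel, kernel, stride, stride)
    N, C = xp.shape[:2]
    flat = windows.reshape(N, C, kernel * kernel, Ho, Wo)
    arg = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        gx = np.zeros_like(xp.data, dtype=g.dtype)
        ki, kj = np.unravel_index(arg, (kernel, kernel))
        n, c, oi, oj = np.indices(arg.shape, sparse=False)
        np.add.at(gx, (n, c, oi * stride + ki, oj * stride + kj), g)
        xp._accumulate(gx)

    return Tensor._make(out_data, (xp,), backward)


def _interp_matrix(out_size: int, in_size: int, dtype) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel convention)."""
    A = np.zeros((out_size, in_size), dtype=dtype)
    if in_size == 1:
        A[:, 0] = 1.0
        return A
    scale = in_size / out_size
    for i in range(out_size):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), in_size - 1)
        lo = int(np.floor(src))
        hi = min(lo + 1, in_size - 1)
        t = src - lo
        A[i, lo] += 1.0 - t
        A[i, hi] += t
    return A


def _pool_matrix(out_size: int, in_size: int, dtype) -> np.ndarray:
    """Adaptive average pooling matrix (floor/ceil bin convention)."""
    A = np.zeros((out_size, in_size), dtype=dtype)
    for i in range(out_size):
        a = (i * in_size) // out_size
        b = -((-(i + 1) * in_size) // out_size)  # ceil
        A[i, a:b] = 1.0 / (b - a)
    return A


def _apply_spatial_matrices(x: Tensor, Ah: np.ndarray, Aw: np.ndarray) -> Tensor:
    N, C, H, W = x.shape
    flat = x.reshape(N * C, H, W)
    out = Tensor(Ah) @ flat @ Tensor(Aw.T)
    return out.reshape(N, C, Ah.shape[0], Aw.shape[0])


def interpolate_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    dt = x.dtype if x.dtype.kind == "f" else np.float64
    return _apply_spatial_matrices(x, _interp_matrix(out_h, x.shape[-2], dt),
                                   _interp_matrix(out_w, x.shape[-1], dt))


def adaptive_avg_pool2d(x: Tensor, out_h: int, out_w: int) -> Tensor:
    dt = x.dtype if x.dtype.kind == "f" else np.float64
    return _apply_spatial_matrices(x, _pool_matrix(out_h, x.shape[-2], dt),
                                   _pool_matrix(out_w, x.shape[-1], dt))
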