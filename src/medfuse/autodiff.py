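"""Compact reverse-mode automatic differentiation over NumPy arrays.

Provides the small set of differentiable primitives the fusion network
needs: broadcast arithmetic, matmul, reductions, reshapes, stable softmax,
2-D convolution (shared-weight and per-sample-weight), padding/unfolding,
and the pointwise nonlinearities (GELU, sigmoid, tanh, ReLU).

Gradients are accumulated into ``Tensor.grad`` (a NumPy array) by calling
``backward()`` on a scalar. The graph is built eagerly; no tapes or
retained sessions. Everything is float64 unless the caller passes float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "softmax",
    "gelu",
    "relu",
    "sigmoid",
    "pad2d",
    "conv2d",
    "conv2d_samplewise",
    "unfold2d",
    "embedding",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        if isinstance(other, (int, float)):
            def bws(g):
                self._accumulate(g)

            return Tensor(self.data + other, parents=(self,), backward=bws)
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            def bws(g):
                self._accumulate(g * other)

            return Tensor(self.data * other, parents=(self,), backward=bws)
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            out_data = other / self.data

            def bws(g):
                self._accumulate(-g * out_data / self.data)

            return Tensor(out_data, parents=(self,), backward=bws)
        return as_tensor(other) / self

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(out_data, parents=(self,), backward=bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.expand_dims(g, -1) * other.data
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.expand_dims(self.data, -1) * np.expand_dims(g, -2)
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    # -------------------------------------------------------------- pointwise
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor(out_data, parents=(self,), backward=bw)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                axes = tuple(a % self.data.ndim for a in axes)
                g = np.expand_dims(g, tuple(sorted(axes)))
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accumulate(g.reshape(old_shape))

        return Tensor(out_data, parents=(self,), backward=bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            self._accumulate(gx)

        return Tensor(out_data, parents=(self,), backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


# ---------------------------------------------------------------- functional
def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate(y * (g - dot))

    return Tensor(y, parents=(x,), backward=bw)


_SQRT2 = float(np.sqrt(2.0))
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = as_tensor(x)
    phi = 0.5 * (1.0 + _erf(x.data / _SQRT2))
    out_data = x.data * phi

    def bw(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x.data**2)
        x._accumulate(g * (phi + x.data * pdf))

    return Tensor(out_data, parents=(x,), backward=bw)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def bw(g):
        x._accumulate(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=bw)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    y = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x._accumulate(g * y * (1.0 - y))

    return Tensor(y, parents=(x,), backward=bw)


def pad2d(x: Tensor, pad, mode: str = "constant", axes=(-2, -1)) -> Tensor:
    """Pad two axes of ``x`` by ``pad = (before_h, after_h, before_w, after_w)``.

    ``mode`` is "constant" (zeros) or "reflect". Reflection gradients are
    scatter-added back through the index map.
    """
    x = as_tensor(x)
    bh, ah, bw_, aw = pad
    ax_h = axes[0] % x.ndim
    ax_w = axes[1] % x.ndim
    if (bh, ah, bw_, aw) == (0, 0, 0, 0):
        return x
    H = x.shape[ax_h]
    W = x.shape[ax_w]
    if mode == "constant":
        widths = [(0, 0)] * x.ndim
        widths[ax_h] = (bh, ah)
        widths[ax_w] = (bw_, aw)
        out_data = np.pad(x.data, widths)
        sl = [slice(None)] * x.ndim
        sl[ax_h] = slice(bh, bh + H)
        sl[ax_w] = slice(bw_, bw_ + W)
        sl = tuple(sl)

        def bw(g):
            x._accumulate(g[sl])

        return Tensor(out_data, parents=(x,), backward=bw)
    if mode != "reflect":
        raise ValueError(f"unknown pad mode {mode!r}")
    idx_h = np.pad(np.arange(H), (bh, ah), mode="reflect")
    idx_w = np.pad(np.arange(W), (bw_, aw), mode="reflect")
    index = [slice(None)] * x.ndim
    index[ax_h] = idx_h[:, None]
    index[ax_w] = idx_w[None, :]
    index = tuple(index)
    out_data = x.data[index]

    def bw(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, index, g)
        x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=bw)


def conv2d(x: Tensor, w: Tensor, bias: Tensor | None = None, padding: int = 0) -> Tensor:
    """2-D cross-correlation, stride 1. ``x``: (B,C,H,W); ``w``: (O,C,kh,kw)."""
    x = as_tensor(x)
    w = as_tensor(w)
    _, _, kh, kw = w.shape
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # B,C,Ho,Wo,kh,kw
    out_data = np.einsum("bchwij,ocij->bohw", win, w.data, optimize=True)
    parents = [x, w]
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
        parents.append(bias)

    def bw(g):
        if w.requires_grad:
            w._accumulate(np.einsum("bchwij,bohw->ocij", win, g, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            q = (kh - 1 - p, kw - 1 - p)
            gp = np.pad(g, ((0, 0), (0, 0), (q[0], q[0]), (q[1], q[1])))
            gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
            wf = w.data[:, :, ::-1, ::-1]
            x._accumulate(np.einsum("bohwij,ocij->bchw", gwin, wf, optimize=True))

    return Tensor(out_data, parents=tuple(parents), backward=bw)


def conv2d_samplewise(x: Tensor, w: Tensor, bias: Tensor | None = None, padding: int = 0) -> Tensor:
    """Convolution with a different kernel per batch sample.

    ``x``: (B,C,H,W); ``w``: (B,O,C,kh,kw). Used by the dynamic convolution,
    where the aggregated kernel is input-conditioned.
    """
    x = as_tensor(x)
    w = as_tensor(w)
    _, _, _, kh, kw = w.shape
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    out_data = np.einsum("bchwij,bocij->bohw", win, w.data, optimize=True)
    parents = [x, w]
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
        parents.append(bias)

    def bw(g):
        if w.requires_grad:
            w._accumulate(np.einsum("bchwij,bohw->bocij", win, g, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            q = (kh - 1 - p, kw - 1 - p)
            gp = np.pad(g, ((0, 0), (0, 0), (q[0], q[0]), (q[1], q[1])))
            gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
            wf = w.data[:, :, :, ::-1, ::-1]
            x._accumulate(np.einsum("bohwij,bocij->bchw", gwin, wf, optimize=True))

    return Tensor(out_data, parents=tuple(parents), backward=bw)


def unfold2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """Extract (possibly overlapping) ``kernel``×``kernel`` patches.

    ``x``: (B,C,H,W) → (B,C,nH,nW,kernel,kernel) with zero padding. This is
    the key/value extraction step of overlapping cross attention.
    """
    x = as_tensor(x)
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    out_data = np.ascontiguousarray(win)
    Hp = xp.shape[2]
    Wp = xp.shape[3]

    def bw(g):
        gxp = np.zeros((x.shape[0], x.shape[1], Hp, Wp), dtype=x.data.dtype)
        nH, nW = g.shape[2], g.shape[3]
        for i in range(kernel):
            for j in range(kernel):
                gxp[:, :, i : i + nH * stride : stride, j : j + nW * stride : stride] += g[:, :, :, :, i, j]
        if p:
            gxp = gxp[:, :, p:-p, p:-p]
        x._accumulate(gxp)

    return Tensor(out_data, parents=(x,), backward=bw)


def embedding(table: Tensor, index: np.ndarray) -> Tensor:
    """Gather rows of ``table`` by an integer index array (not differentiable
    in the index). Used for relative position bias lookup."""
    table = as_tensor(table)
    out_data = table.data[index]

    def bw(g):
        gt = np.zeros_like(table.data)
        np.add.at(gt, index, g)
        table._accumulate(gt)

    return Tensor(out_data, parents=(table,), backward=bw)
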