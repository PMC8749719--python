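"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module implements exactly the operator set the fusion networks and
their composite loss need: elementwise arithmetic with broadcasting,
``log``/``sqrt``/``abs``/``clip``, leaky ReLU and sigmoid, axis reductions,
channel concatenation, basic slicing, matrix multiplication, and 2-D
convolution (im2col lowered onto BLAS ``matmul``).  Gradients follow the
usual vector-Jacobian-product recipe with a topological-order sweep.

Arrays keep the dtype they are given: training runs in float32 for speed,
while the public loss/metric wrappers feed float64 so that closed-form
oracle comparisons hold to tight tolerances.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: Optional[np.ndarray] = None
        self._parents: Tuple["Tensor", ...] = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return add(self, -other)
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(astensor(other), self)

    def __pow__(self, k):
        return power(self, k)

    def __getitem__(self, idx):
        return getitem(self, idx)


# ----------------------------------------------------------------------
def astensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=dtype)
    return Tensor(arr)


def _make(data: np.ndarray, parents: Tuple[Tensor, ...], backward) -> Tensor:
    t = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        t.requires_grad = True
        t._parents = parents
        t._backward = backward
    return t


def _unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# elementwise ----------------------------------------------------------
# Python int/float operands take a fast path that keeps them as weak
# scalars, so float32 graphs are not silently promoted to float64.
def add(a, b) -> Tensor:
    if isinstance(b, (int, float)) and isinstance(a, Tensor):
        out = a.data + b

        def backward_s(g):
            return (g,)

        return _make(out, (a,), backward_s)
    a, b = astensor(a), astensor(b)
    out = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _make(out, (a, b), backward)


def mul(a, b) -> Tensor:
    if isinstance(b, (int, float)) and isinstance(a, Tensor):
        out = a.data * b

        def backward_s(g):
            return (g * b,)

        return _make(out, (a,), backward_s)
    a, b = astensor(a), astensor(b)
    out = a.data * b.data

    def backward(g):
        return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

    return _make(out, (a, b), backward)


def div(a, b) -> Tensor:
    if isinstance(b, (int, float)) and isinstance(a, Tensor):
        return mul(a, 1.0 / b)
    a, b = astensor(a), astensor(b)
    out = a.data / b.data

    def backward(g):
        ga = _unbroadcast(g / b.data, a.shape)
        gb = _unbroadcast(-g * a.data / (b.data * b.data), b.shape)
        return ga, gb

    return _make(out, (a, b), backward)


def power(a, k: float) -> Tensor:
    a = astensor(a)
    out = a.data**k

    def backward(g):
        return (g * k * a.data ** (k - 1.0),)

    return _make(out, (a,), backward)


def log(a) -> Tensor:
    a = astensor(a)
    out = np.log(a.data)

    def backward(g):
        return (g / a.data,)

    return _make(out, (a,), backward)


def sqrt(a) -> Tensor:
    a = astensor(a)
    y = np.sqrt(a.data)

    def backward(g):
        return (g * 0.5 / y,)

    return _make(y, (a,), backward)


def absolute(a) -> Tensor:
    a = astensor(a)
    out = np.abs(a.data)

    def backward(g):
        return (g * np.sign(a.data),)

    return _make(out, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    a = astensor(a)
    out = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        return (g * mask,)

    return _make(out, (a,), backward)


def sigmoid(a) -> Tensor:
    a = astensor(a)
    y = expit(a.data)

    def backward(g):
        return (g * y * (1.0 - y),)

    return _make(y, (a,), backward)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = astensor(a)
    pos = a.data >= 0
    out = np.where(pos, a.data, a.data * slope)

    def backward(g):
        return (np.where(pos, g, g * slope),)

    return _make(out, (a,), backward)


# shape ops ------------------------------------------------------------
def reshape(a, shape) -> Tensor:
    a = astensor(a)
    out = a.data.reshape(shape)

    def backward(g):
        return (g.reshape(a.shape),)

    return _make(out, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    ts = [astensor(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(out, tuple(ts), backward)


def getitem(a, idx) -> Tensor:
    a = astensor(a)
    out = a.data[idx]

    def backward(g):
        z = np.zeros_like(a.data)
        z[idx] += g
        return (z,)

    return _make(out, (a,), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        gx = g
        if not keepdims:
            gx = np.expand_dims(gx, axis)
        return (np.broadcast_to(gx, a.shape).copy(),)

    return _make(out, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data @ b.data

    def backward(g):
        return g @ b.data.T, a.data.T @ g

    return _make(out, (a, b), backward)


# convolution ----------------------------------------------------------
def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation over NCHW batches (im2col + BLAS matmul).

    Columns are laid out channel-major, (B, C*KH*KW, OH*OW), so neither the
    forward product nor the backward scatter needs a transposed copy.
    """
    x, w = astensor(x), astensor(w)
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    O, Ci, KH, KW = wd.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, kernel {Ci}")
    s, p = int(stride), int(padding)
    if p:
        xp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=xd.dtype)
        xp[:, :, p : p + H, p : p + W] = xd
    else:
        xp = xd
    OH = (H + 2 * p - KH) // s + 1
    OW = (W + 2 * p - KW) // s + 1
    cols = np.empty((B, C, KH * KW, OH, OW), dtype=xd.dtype)
    for kh in range(KH):
        for kw in range(KW):
            cols[:, :, kh * KW + kw] = xp[:, :, kh : kh + s * OH : s, kw : kw + s * OW : s]
    cols = cols.reshape(B, C * KH * KW, OH * OW)
    wmat = wd.reshape(O, C * KH * KW)
    out = np.matmul(wmat, cols).reshape(B, O, OH, OW)
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)

    def backward(g):
        g2 = g.reshape(B, O, OH * OW)
        gw = None
        if w.requires_grad:
            gw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(wd.shape)
        gx = None
        if x.requires_grad:
            gcols = np.matmul(wmat.T, g2).reshape(B, C, KH * KW, OH, OW)
            gxp = np.zeros_like(xp)
            for kh in range(KH):
                for kw in range(KW):
                    gxp[:, :, kh : kh + s * OH : s, kw : kw + s * OW : s] += gcols[:, :, kh * KW + kw]
            gx = gxp[:, :, p : p + H, p : p + W] if p else gxp
        if b is None:
            return gx, gw
        gb = g.sum(axis=(0, 2, 3)).reshape(b.data.shape) if b.requires_grad else None
        return gx, gw, gb

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)
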