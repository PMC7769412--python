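"""Minimal reverse-mode automatic differentiation over numpy arrays.

Internal engine used by the loss functions, the feature extractor and the
correction network.  It implements exactly the primitives those components
need (elementwise arithmetic, reductions, matmul, 3x3 convolution, 2x2 max
pooling, nearest-neighbour upsampling) on single images laid out as
``(C, H, W)`` arrays — no batch axis, no broadcasting surprises.

Graphs are only recorded when an input tensor has ``requires_grad=True``;
pure inference therefore runs at plain-numpy cost.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "conv2d", "maxpool2", "upsample2"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=self.data.dtype), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- elementwise arithmetic --------------------------------------------
    # Python int/float operands are treated as dtype-preserving scalar
    # constants (a bare float would otherwise promote float32 graphs to
    # float64 through numpy's 0-d array rules).
    def __add__(self, other):
        if isinstance(other, (int, float)):
            c = self.data.dtype.type(other)
            out = Tensor._make(self.data + c, (self,), None)
            if out.requires_grad:
                out._backward = lambda g: self._accum(g)
            return out
        o = as_tensor(other)
        out = Tensor._make(self.data + o.data, (self, o), None)
        if out.requires_grad:
            def back(g):
                self._accum(g)
                o._accum(g)
            out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            c = self.data.dtype.type(other)
            out = Tensor._make(c - self.data, (self,), None)
            if out.requires_grad:
                out._backward = lambda g: self._accum(-g)
            return out
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            c = self.data.dtype.type(other)
            out = Tensor._make(self.data * c, (self,), None)
            if out.requires_grad:
                out._backward = lambda g: self._accum(g * c)
            return out
        o = as_tensor(other)
        out = Tensor._make(self.data * o.data, (self, o), None)
        if out.requires_grad:
            def back(g):
                self._accum(g * o.data)
                o._accum(g * self.data)
            out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        o = as_tensor(other)
        out = Tensor._make(self.data / o.data, (self, o), None)
        if out.requires_grad:
            def back(g):
                self._accum(g / o.data)
                o._accum(-g * self.data / (o.data * o.data))
            out._backward = back
        return out

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            c = self.data.dtype.type(other)
            y = c / self.data
            out = Tensor._make(y, (self,), None)
            if out.requires_grad:
                out._backward = lambda g: self._accum(-g * y / self.data)
            return out
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor._make(self.data ** exponent, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(
                g * exponent * self.data ** (exponent - 1)
            )
        return out

    # -- unary functions ---------------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor._make(y, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor._make(y, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / (2.0 * y))
        return out

    def abs(self):
        out = Tensor._make(np.abs(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    def clamp_min(self, floor: float):
        mask = self.data >= floor
        out = Tensor._make(np.maximum(self.data, floor), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            def back(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
            out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def _extreme(self, axis, keepdims, fn):
        y = fn(self.data, axis=axis, keepdims=True)
        out_data = y if keepdims else np.squeeze(y, axis=axis) if axis is not None else y.reshape(())
        out = Tensor._make(out_data, (self,), None)
        if out.requires_grad:
            mask = (self.data == y)
            counts = mask.sum(axis=axis, keepdims=True)

            def back(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(mask * (g / counts))
            out._backward = back
        return out

    def max(self, axis=None, keepdims: bool = False):
        return self._extreme(axis, keepdims, np.max)

    def min(self, axis=None, keepdims: bool = False):
        return self._extreme(axis, keepdims, np.min)

    # -- linear algebra / shape --------------------------------------------
    def matmul(self, other):
        o = as_tensor(other)
        out = Tensor._make(self.data @ o.data, (self, o), None)
        if out.requires_grad:
            def back(g):
                self._accum(g @ o.data.T)
                o._accum(self.data.T @ g)
            out._backward = back
        return out

    __matmul__ = matmul

    @property
    def T(self):
        out = Tensor._make(self.data.T, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.T)
        return out

    def reshape(self, *shape):
        out = Tensor._make(self.data.reshape(*shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- image primitives ------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, oh: int, ow: int):
    c = xp.shape[0]
    cols = np.empty((c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, i, j] = xp[:, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(c * kh * kw, oh * ow)


def _col2im(dcols, c, hp, wp, kh, kw, stride, oh, ow):
    dxp = np.zeros((c, hp, wp), dtype=dcols.dtype)
    dcols = dcols.reshape(c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[:, i, j]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), x: (C,H,W), w: (Cout,Cin,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    c, h, wid = x.data.shape
    cout, cin, kh, kw = w.data.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, kernel expects {cin}")
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad))) if pad else x.data
    hp, wp = xp.shape[1:]
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride, oh, ow)
    wf = w.data.reshape(cout, cin * kh * kw)
    y = (wf @ cols).reshape(cout, oh, ow)
    parents = (x, w) if b is None else (x, w, as_tensor(b))
    if b is not None:
        bt = parents[2]
        y = y + bt.data.reshape(cout, 1, 1)
    out = Tensor._make(y, parents, None)
    if out.requires_grad:
        def back(g):
            gf = g.reshape(cout, oh * ow)
            if b is not None:
                parents[2]._accum(gf.sum(axis=1))
            if w.requires_grad:
                w._accum((gf @ cols.T).reshape(w.data.shape))
            if x.requires_grad:
                dxp = _col2im(wf.T @ gf, c, hp, wp, kh, kw, stride, oh, ow)
                x._accum(dxp[:, pad : hp - pad, pad : wp - pad] if pad else dxp)
        out._backward = back
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    x = as_tensor(x)
    c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {h}x{w}")
    r = x.data.reshape(c, h // 2, 2, w // 2, 2)
    y = r.max(axis=(2, 4))
    out = Tensor._make(y, (x,), None)
    if out.requires_grad:
        mask = r == y[:, :, None, :, None]
        counts = mask.sum(axis=(2, 4), keepdims=True)

        def back(g):
            gr = mask * (g[:, :, None, :, None] / counts)
            x._accum(gr.reshape(c, h, w))
        out._backward = back
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    x = as_tensor(x)
    c, h, w = x.data.shape
    y = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)
    out = Tensor._make(y, (x,), None)
    if out.requires_grad:
        def back(g):
            x._accum(g.reshape(c, h, 2, w, 2).sum(axis=(2, 4)))
        out._backward = back
    return out
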