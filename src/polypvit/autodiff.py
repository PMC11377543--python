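"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations needed by the segmentation model are provided.  Every
public function accepts either plain ``numpy.ndarray`` (or scalar) inputs, in
which case it computes with NumPy and returns an array, or :class:`Tensor`
inputs, in which case the result is a tensor wired into the computation
graph.  This lets the numerical routines of the model be written once and be
reused both as plain-array oracles and as differentiable training code.

All tensors are float64.  Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward`, which topologically sorts the graph reachable from
the output and applies each node's vector-Jacobian product once.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "is_tensor",
    "astensor",
    "parameter",
    "add", "sub", "mul", "div", "neg", "power",
    "exp", "log", "sqrt", "tanh", "absolute", "maximum", "minimum",
    "matmul", "tsum", "tmean", "reshape", "transpose", "getitem", "concat",
    "relu", "gelu", "softmax", "sigmoid",
    "conv2d", "translate2d", "bilinear_shift2d",
]


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


class Tensor:
    """A NumPy array plus the bookkeeping for reverse-mode differentiation."""

    __array_priority__ = 1000.0
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = ()
        self._backward = None

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- graph ------------------------------------------------------------
    def backward(self, grad=None) -> None:
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ---------------------------------------------------
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

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, c):
        return power(self, c)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes if axes else None)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def astensor(x) -> Tensor:
    return x if is_tensor(x) else Tensor(x)


def parameter(data) -> Tensor:
    """A leaf tensor that accumulates gradients."""
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


# ---------------------------------------------------------------------------
# graph construction helpers

def _accum(t: Tensor, g) -> None:
    # closures never mutate gradient arrays in place, so aliasing is safe
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g if isinstance(g, np.ndarray) else np.asarray(g, dtype=np.float64)
    else:
        t.grad = t.grad + g


_grad_enabled = True


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``g`` (gradient of a broadcast result) back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _any_tensor(*xs) -> bool:
    return any(is_tensor(x) for x in xs)


# ---------------------------------------------------------------------------
# elementwise binary operations

def add(a, b):
    if not _any_tensor(a, b):
        return np.add(a, b)
    a, b = astensor(a), astensor(b)

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), bwd)


def sub(a, b):
    if not _any_tensor(a, b):
        return np.subtract(a, b)
    a, b = astensor(a), astensor(b)

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _make(a.data - b.data, (a, b), bwd)


def mul(a, b):
    if not _any_tensor(a, b):
        return np.multiply(a, b)
    a, b = astensor(a), astensor(b)

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), bwd)


def div(a, b):
    if not _any_tensor(a, b):
        return np.divide(a, b)
    a, b = astensor(a), astensor(b)

    def bwd(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _make(a.data / b.data, (a, b), bwd)


def neg(a):
    if not is_tensor(a):
        return np.negative(a)

    def bwd(g):
        _accum(a, -g)

    return _make(-a.data, (a,), bwd)


def power(a, c: float):
    """Elementwise a**c for a constant exponent c."""
    if not is_tensor(a):
        return np.power(a, c)

    def bwd(g):
        _accum(a, g * c * np.power(a.data, c - 1))

    return _make(np.power(a.data, c), (a,), bwd)


def maximum(a, b):
    if not _any_tensor(a, b):
        return np.maximum(a, b)
    a, b = astensor(a), astensor(b)
    mask = a.data >= b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * mask, a.data.shape))
        _accum(b, _unbroadcast(g * ~mask, b.data.shape))

    return _make(np.maximum(a.data, b.data), (a, b), bwd)


def minimum(a, b):
    if not _any_tensor(a, b):
        return np.minimum(a, b)
    a, b = astensor(a), astensor(b)
    mask = a.data <= b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * mask, a.data.shape))
        _accum(b, _unbroadcast(g * ~mask, b.data.shape))

    return _make(np.minimum(a.data, b.data), (a, b), bwd)


# ---------------------------------------------------------------------------
# elementwise unary operations

def exp(a):
    if not is_tensor(a):
        return np.exp(a)
    out_data = np.exp(a.data)

    def bwd(g):
        _accum(a, g * out_data)

    return _make(out_data, (a,), bwd)


def log(a):
    if not is_tensor(a):
        return np.log(a)

    def bwd(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), bwd)


def sqrt(a):
    if not is_tensor(a):
        return np.sqrt(a)
    out_data = np.sqrt(a.data)

    def bwd(g):
        _accum(a, g * 0.5 / out_data)

    return _make(out_data, (a,), bwd)


def tanh(a):
    if not is_tensor(a):
        return np.tanh(a)
    out_data = np.tanh(a.data)

    def bwd(g):
        _accum(a, g * (1.0 - out_data ** 2))

    return _make(out_data, (a,), bwd)


def absolute(a):
    if not is_tensor(a):
        return np.abs(a)
    sign = np.sign(a.data)

    def bwd(g):
        _accum(a, g * sign)

    return _make(np.abs(a.data), (a,), bwd)


def sigmoid(a):
    if not is_tensor(a):
        return 1.0 / (1.0 + np.exp(-a))
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bwd)


# ---------------------------------------------------------------------------
# reductions and shape operations

def tsum(a, axis=None, keepdims=False):
    if not is_tensor(a):
        return np.sum(a, axis=axis, keepdims=keepdims)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
            return
        gg = g
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(ax % a.data.ndim for ax in axes):
                gg = np.expand_dims(gg, ax)
        _accum(a, np.broadcast_to(gg, a.data.shape).copy())

    return _make(out_data, (a,), bwd)


def tmean(a, axis=None, keepdims=False):
    if not is_tensor(a):
        return np.mean(a, axis=axis, keepdims=keepdims)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return div(tsum(a, axis=axis, keepdims=keepdims), float(n))


def reshape(a, shape):
    if not is_tensor(a):
        return np.reshape(a, shape)
    old_shape = a.data.shape

    def bwd(g):
        _accum(a, g.reshape(old_shape))

    return _make(a.data.reshape(shape), (a,), bwd)


def transpose(a, axes=None):
    if not is_tensor(a):
        return np.transpose(a, axes)
    if axes is None:
        axes = tuple(reversed(range(a.data.ndim)))
    inv = tuple(np.argsort(axes))

    def bwd(g):
        _accum(a, g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), bwd)


def getitem(a, idx):
    if not is_tensor(a):
        return a[idx]

    def bwd(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        _accum(a, full)

    return _make(a.data[idx], (a,), bwd)


def concat(parts, axis=0):
    if not _any_tensor(*parts):
        return np.concatenate(parts, axis=axis)
    parts = [astensor(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(p, g[tuple(sl)])

    return _make(np.concatenate([p.data for p in parts], axis=axis), tuple(parts), bwd)


def matmul(a, b):
    if not _any_tensor(a, b):
        return np.matmul(a, b)
    a, b = astensor(a), astensor(b)

    def bwd(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            _accum(a, _unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            _accum(b, _unbroadcast(gb, b.data.shape))

    return _make(np.matmul(a.data, b.data), (a, b), bwd)


# ---------------------------------------------------------------------------
# nonlinearities

def relu(a):
    return maximum(a, 0.0)


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(a):
    """Tanh approximation of the Gaussian error linear unit."""
    cube = mul(a, mul(a, a))  # a**3 via multiplies (np.power is slow)
    inner = mul(_GELU_C, add(a, mul(0.044715, cube)))
    return mul(mul(0.5, a), add(1.0, tanh(inner)))


def softmax(a, axis=-1):
    """Numerically stable softmax along ``axis``."""
    if is_tensor(a):
        shift = np.max(a.data, axis=axis, keepdims=True)  # constant shift
        e = exp(sub(a, shift))
    else:
        e = np.exp(a - np.max(a, axis=axis, keepdims=True))
    return div(e, tsum(e, axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# structured image operations

def _conv2d_forward(x, w, stride, padding):
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c} vs kernel {c2}")
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (wd + 2 * padding - kw) // stride + 1
    out = np.zeros((n, o, oh, ow))
    for i in range(kh):
        for j in range(kw):
            window = xp[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride]
            out += np.einsum("nchw,oc->nohw", window, w[:, :, i, j], optimize=True)
    return out, xp, (oh, ow)


def conv2d(x, w, stride: int = 1, padding: int = 0):
    """2-D cross-correlation over NCHW input with an OCHW kernel."""
    if not _any_tensor(x, w):
        out, _, _ = _conv2d_forward(x, w, stride, padding)
        return out
    x, w = astensor(x), astensor(w)
    out_data, xp, (oh, ow) = _conv2d_forward(x.data, w.data, stride, padding)
    kh, kw = w.data.shape[2:]

    def bwd(g):
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    window = xp[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride]
                    gw[:, :, i, j] = np.einsum("nohw,nchw->oc", g, window, optimize=True)
            _accum(w, gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride] += \
                        np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            _accum(x, gxp)

    return _make(out_data, (x, w), bwd)


def _translate_forward(x, dr, dc):
    n, c, h, w = x.shape
    out = np.zeros_like(x)
    for k in range(n):
        r0, r1 = max(0, -dr[k]), min(h, h - dr[k])
        c0, c1 = max(0, -dc[k]), min(w, w - dc[k])
        if r0 < r1 and c0 < c1:
            out[k, :, r0:r1, c0:c1] = x[k, :, r0 + dr[k]:r1 + dr[k], c0 + dc[k]:c1 + dc[k]]
    return out


def translate2d(x, dr, dc):
    """Integer translation with zero fill: out[n,:,r,c] = x[n,:,r+dr[n],c+dc[n]].

    ``dr``/``dc`` are integer arrays of length N (or scalars); they are
    treated as constants, so gradients flow only through ``x``.
    """
    xa = x.data if is_tensor(x) else np.asarray(x, dtype=np.float64)
    n = xa.shape[0]
    dr = np.broadcast_to(np.asarray(dr, dtype=int), (n,)).copy()
    dc = np.broadcast_to(np.asarray(dc, dtype=int), (n,)).copy()
    if not is_tensor(x):
        return _translate_forward(xa, dr, dc)

    def bwd(g):
        _accum(x, _translate_forward(g, -dr, -dc))

    return _make(_translate_forward(xa, dr, dc), (x,), bwd)


def bilinear_shift2d(x, dr, dc):
    """Sample x at coordinates shifted by per-image fractional (dr, dc).

    out[n,:,r,c] = x[n,:, r+dr[n], c+dc[n]] with bilinear interpolation and
    zero padding outside the frame.  ``dr``/``dc`` may be length-N tensors;
    gradients flow through both the image and the shifts (the integer floor
    of the shift is treated as locally constant).
    """
    dr_t, dc_t = astensor(dr), astensor(dc)
    xa = x.data if is_tensor(x) else np.asarray(x, dtype=np.float64)
    n = xa.shape[0]
    dr_d = np.broadcast_to(np.atleast_1d(dr_t.data), (n,))
    dc_d = np.broadcast_to(np.atleast_1d(dc_t.data), (n,))
    h, w = xa.shape[-2:]
    # non-finite shifts: floor at 0 so indexing stays sane; the fractional
    # part keeps the NaN, which propagates to the output as it should
    lim = float(max(h, w) + 1)
    fr = np.floor(np.clip(np.nan_to_num(dr_d, nan=0.0), -lim, lim)).astype(int)
    fc = np.floor(np.clip(np.nan_to_num(dc_d, nan=0.0), -lim, lim)).astype(int)
    # fractional parts as differentiable functions of the shifts
    a = sub(dr_t, fr.astype(float))
    b = sub(dc_t, fc.astype(float))
    if is_tensor(a):
        a = reshape(a, (n, 1, 1, 1) if a.data.size == n else (1, 1, 1, 1))
        b = reshape(b, (n, 1, 1, 1) if b.data.size == n else (1, 1, 1, 1))
    else:
        a = np.broadcast_to(np.atleast_1d(a), (n,)).reshape(n, 1, 1, 1)
        b = np.broadcast_to(np.atleast_1d(b), (n,)).reshape(n, 1, 1, 1)
    t00 = translate2d(x, fr, fc)
    t10 = translate2d(x, fr + 1, fc)
    t01 = translate2d(x, fr, fc + 1)
    t11 = translate2d(x, fr + 1, fc + 1)
    one = 1.0
    out = add(
        add(mul(mul(sub(one, a), sub(one, b)), t00), mul(mul(a, sub(one, b)), t10)),
        add(mul(mul(sub(one, a), b), t01), mul(mul(a, b), t11)),
    )
    if not _any_tensor(x, dr, dc) and is_tensor(out):
        return out.data
    return out
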