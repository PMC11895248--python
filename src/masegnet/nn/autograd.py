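"""Reverse-mode autodiff core: Tensor nodes and differentiable ops.

Every op returns a new `Tensor` whose `_backward` closure scatters the
output gradient onto its parents.  Gradients accumulate additively, so a
tensor used twice (e.g. a skip connection) receives the sum of both path
gradients.  Inside a `no_grad()` block no graph is built, which is used
for inference.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer mixed ndarray/Tensor arithmetic to our operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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

    def zero_grad(self) -> None:
        self.grad = None

    # convenience operators -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    track = grad_enabled() and any(p.requires_grad for p in parents)
    if track:
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `g` down to `shape` to undo numpy broadcasting."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# elementwise ---------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    pos = x.data > 0

    def backward(g):
        x.accumulate(g * pos)

    return _make(np.where(pos, x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    # piecewise form avoids exp overflow for large |x|
    v = x.data
    s = np.empty_like(v)
    pos = v >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ex = np.exp(v[~pos])
    s[~pos] = ex / (1.0 + ex)

    def backward(g):
        x.accumulate(g * s * (1.0 - s))

    return _make(s, (x,), backward)


def log(x: Tensor) -> Tensor:
    x = _as_tensor(x)

    def backward(g):
        x.accumulate(g / x.data)

    return _make(np.log(x.data), (x,), backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    x = _as_tensor(x)
    inside = (x.data > lo) & (x.data < hi)

    def backward(g):
        x.accumulate(g * inside)

    return _make(np.clip(x.data, lo, hi), (x,), backward)


def power(x: Tensor, p: float) -> Tensor:
    x = _as_tensor(x)

    def backward(g):
        x.accumulate(g * p * np.power(x.data, p - 1.0))

    return _make(np.power(x.data, p), (x,), backward)


# reductions ----------------------------------------------------------------

def mean(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    n = x.data.size

    def backward(g):
        x.accumulate(np.full_like(x.data, float(g) / n))

    return _make(np.asarray(x.data.mean(), dtype=x.data.dtype), (x,), backward)


def sum_(x: Tensor) -> Tensor:
    x = _as_tensor(x)

    def backward(g):
        x.accumulate(np.full_like(x.data, float(g)))

    return _make(np.asarray(x.data.sum(), dtype=x.data.dtype), (x,), backward)


def mean_axes(x: Tensor, axes: tuple[int, ...], keepdims: bool = True) -> Tensor:
    x = _as_tensor(x)
    n = int(np.prod([x.shape[a] for a in axes]))
    out = x.data.mean(axis=axes, keepdims=keepdims)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        x.accumulate(np.broadcast_to(g / n, x.shape).copy())

    return _make(out, (x,), backward)


def max_axes(x: Tensor, axes: tuple[int, ...], keepdims: bool = True) -> Tensor:
    """Max over `axes`; ties share the gradient equally (a valid
    subgradient, and deterministic)."""
    x = _as_tensor(x)
    out = x.data.max(axis=axes, keepdims=True)
    mask = (x.data == out)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        counts = mask.sum(axis=axes, keepdims=True)
        x.accumulate(mask * (g / counts))

    res = out if keepdims else out.squeeze(axis=axes)
    return _make(res, (x,), backward)


# shape ---------------------------------------------------------------------

def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    x = _as_tensor(x)
    old = x.shape

    def backward(g):
        x.accumulate(g.reshape(old))

    return _make(x.data.reshape(shape), (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t.accumulate(p)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


# linear algebra ------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ g)

    return _make(a.data @ b.data, (a, b), backward)


# convolution / pooling -----------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int) -> tuple[np.ndarray, tuple]:
    """Flatten all kh x kw windows of a padded (B,C,Hp,Wp) batch into a
    (B*H*W, C*kh*kw) matrix so convolution becomes one GEMM."""
    view = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # B,C,H,W,kh,kw
    bsz, c, h, w = view.shape[:4]
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(bsz * h * w, c * kh * kw), (bsz, c, h, w)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: int = 0) -> Tensor:
    """Stride-1 2D convolution (cross-correlation), zero padding.

    im2col + GEMM; the column matrix is cached for the weight-gradient
    GEMM and the input gradient is scattered back window-by-window
    (kh*kw strided adds), avoiding a second im2col pass.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    kh, kw = w.shape[2], w.shape[3]
    cout = w.shape[0]
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    cols, (bsz, cin, h, wd) = _im2col(xp, kh, kw)
    wmat = w.data.reshape(cout, -1)
    out = np.ascontiguousarray(
        (cols @ wmat.T).reshape(bsz, h, wd, cout).transpose(0, 3, 1, 2))
    if b is not None:
        b = _as_tensor(b)
        out += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w.accumulate((gm.T @ cols).reshape(w.shape))
        if x.requires_grad:
            gcols = (gm @ wmat).reshape(bsz, h, wd, cin, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + h, j:j + wd] += \
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            x.accumulate(gxp[:, :, p:p + x.shape[2], p:p + x.shape[3]]
                         if p else gxp)

    return _make(out, parents, backward)


def conv_transpose2d_2x(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2 transposed convolution with stride 2 (exact 2x upsampling,
    no output overlap).  w has shape (C_in, C_out, 2, 2)."""
    x, w = _as_tensor(x), _as_tensor(w)
    bsz, cin, h, wd = x.shape
    cout = w.shape[1]
    out6 = np.einsum("bcij,cokl->boikjl", x.data, w.data, optimize=True)
    out = out6.reshape(bsz, cout, 2 * h, 2 * wd)
    if b is not None:
        b = _as_tensor(b)
        out = out + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g6 = g.reshape(bsz, cout, h, 2, wd, 2)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w.accumulate(np.einsum("bcij,boikjl->cokl", x.data, g6,
                                   optimize=True))
        if x.requires_grad:
            x.accumulate(np.einsum("boikjl,cokl->bcij", g6, w.data,
                                   optimize=True))

    return _make(out, parents, backward)


def maxpool2d_2x(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; ties split the gradient."""
    x = _as_tensor(x)
    bsz, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2d_2x needs even spatial dims, got {h}x{w}")
    r = x.data.reshape(bsz, c, h // 2, 2, w // 2, 2)
    out = r.max(axis=(3, 5))
    mask = r == out[:, :, :, None, :, None]

    def backward(g):
        counts = mask.sum(axis=(3, 5), keepdims=True)
        gr = mask * (g[:, :, :, None, :, None] / counts)
        x.accumulate(gr.reshape(bsz, c, h, w))

    return _make(out, (x,), backward)


def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """1D bilinear resampling matrix (half-pixel-centre convention)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resampling of (B,C,H,W) to (B,C,H',W') as a separable
    linear operator, so the backward pass is its exact transpose."""
    x = _as_tensor(x)
    h2, w2 = size
    ry = _interp_matrix(h2, x.shape[2], x.data.dtype)
    rx = _interp_matrix(w2, x.shape[3], x.data.dtype)
    out = np.einsum("ph,bchw,qw->bcpq", ry, x.data, rx, optimize=True)

    def backward(g):
        x.accumulate(np.einsum("ph,bcpq,qw->bchw", ry, g, rx, optimize=True))

    return _make(out, (x,), backward)
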