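"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine exists to support adversarial training of convolutional
image-translation networks on the CPU: it provides exactly the primitive
set those networks need (broadcast arithmetic, matmul, reshape/transpose,
gather/scatter for im2col convolution, reductions, tanh / leaky-relu) and
nothing else.

Design notes
------------
Every vector-Jacobian product is itself expressed in terms of the same
primitives, so gradients are differentiable: ``grad(..., create_graph=True)``
yields a graph through which one can backpropagate again.  This
double-backward capability is what the Wasserstein gradient-penalty term
requires (the critic loss contains the norm of an input gradient, and its
parameter gradient involves mixed second derivatives).

Tensors are thin wrappers over float arrays; a tensor records its parents
and a vjp closure only when some parent requires a gradient and grad mode
is enabled (see :func:`no_grad`).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "parameter",
    "no_grad",
    "grad",
    "backward",
    "add", "sub", "mul", "div", "neg", "power", "exp", "log", "sqrt",
    "tanh", "absolute", "leaky_relu", "relu",
    "matmul", "reshape", "transpose", "sum_", "mean_",
    "concatenate", "pad2d", "getitem", "scatter_slice",
    "take_patches", "put_patches", "dilate2d",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context (inference / detaching)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "requires_grad", "parents", "vjp")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), vjp: Callable | None = None):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data)
        if data.dtype.kind != "f":
            data = data.astype(np.float64)
        self.data = data
        self.requires_grad = requires_grad
        self.parents = parents
        self.vjp = vjp

    # -- introspection -------------------------------------------------
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- operators ------------------------------------------------------
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
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes or None)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)


def astensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64))


def parameter(x) -> Tensor:
    """A leaf tensor that accumulates gradients (float dtype preserved)."""
    x = np.asarray(x)
    if x.dtype.kind != "f":
        x = x.astype(np.float64)
    return Tensor(x.copy(), requires_grad=True)


def _make(data, parents, vjp) -> Tensor:
    if _grad_enabled and any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=tuple(parents), vjp=vjp)
    return Tensor(data)


# ---------------------------------------------------------------------------
# broadcasting helper: reduce g back to `shape` (itself built from primitives
# so it stays differentiable)
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    if g.shape == shape:
        return g
    ndim_extra = g.ndim - len(shape)
    if ndim_extra > 0:
        g = sum_(g, axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# arithmetic primitives
# ---------------------------------------------------------------------------

def _pair(a, b):
    """Coerce operands to tensors; python scalars adopt the partner's dtype
    so float32 graphs are not silently promoted to float64."""
    if isinstance(a, Tensor) and not isinstance(b, Tensor):
        b = Tensor(np.asarray(b, dtype=a.data.dtype))
    elif isinstance(b, Tensor) and not isinstance(a, Tensor):
        a = Tensor(np.asarray(a, dtype=b.data.dtype))
    else:
        a, b = astensor(a), astensor(b)
    return a, b


def add(a, b):
    a, b = _pair(a, b)
    return _make(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def sub(a, b):
    a, b = _pair(a, b)
    return _make(a.data - b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape),
                            _unbroadcast(neg(g), b.shape)))


def mul(a, b):
    a, b = _pair(a, b)
    return _make(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(mul(g, b), a.shape),
                            _unbroadcast(mul(g, a), b.shape)))


def div(a, b):
    a, b = _pair(a, b)
    return _make(a.data / b.data, (a, b),
                 lambda g: (_unbroadcast(div(g, b), a.shape),
                            _unbroadcast(neg(div(mul(g, a), mul(b, b))),
                                         b.shape)))


def neg(a):
    a = astensor(a)
    return _make(-a.data, (a,), lambda g: (neg(g),))


def power(a, p: float):
    a = astensor(a)
    p = float(p)
    return _make(a.data ** p, (a,),
                 lambda g: (mul(g, mul(p, power(a, p - 1.0))),))


def exp(a):
    a = astensor(a)
    out_data = np.exp(a.data)
    return _make(out_data, (a,), lambda g: (mul(g, exp(a)),))


def log(a):
    a = astensor(a)
    return _make(np.log(a.data), (a,), lambda g: (div(g, a),))


def sqrt(a):
    a = astensor(a)
    return _make(np.sqrt(a.data), (a,),
                 lambda g: (div(g, mul(2.0, sqrt(a))),))


def tanh(a):
    a = astensor(a)
    return _make(np.tanh(a.data), (a,),
                 lambda g: (mul(g, sub(1.0, mul(tanh(a), tanh(a)))),))


def absolute(a):
    a = astensor(a)
    sign = np.sign(a.data)  # subgradient 0 at 0
    return _make(np.abs(a.data), (a,), lambda g: (mul(g, Tensor(sign)),))


def leaky_relu(a, slope: float = 0.2):
    a = astensor(a)
    m = np.where(a.data > 0, np.asarray(1.0, dtype=a.data.dtype),
                 np.asarray(slope, dtype=a.data.dtype))
    return _make(a.data * m, (a,), lambda g: (mul(g, Tensor(m)),))


def relu(a):
    return leaky_relu(a, 0.0)


# ---------------------------------------------------------------------------
# shape / linear-algebra primitives
# ---------------------------------------------------------------------------

def matmul(a, b):
    """Batched matrix product (..., n, k) @ (..., k, m), numpy broadcasting."""
    a, b = astensor(a), astensor(b)

    def vjp(g):
        ga = _unbroadcast(matmul(g, _swap_last(b)), a.shape)
        gb = _unbroadcast(matmul(_swap_last(a), g), b.shape)
        return ga, gb

    return _make(a.data @ b.data, (a, b), vjp)


def _swap_last(a: Tensor) -> Tensor:
    axes = list(range(a.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return transpose(a, tuple(axes))


def transpose(a, axes=None):
    a = astensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))
    return _make(np.transpose(a.data, axes), (a,),
                 lambda g: (transpose(g, inv),))


def reshape(a, shape):
    a = astensor(a)
    old = a.shape
    return _make(np.reshape(a.data, shape), (a,),
                 lambda g: (reshape(g, old),))


def sum_(a, axis=None, keepdims=False):
    a = astensor(a)
    out_data = np.sum(a.data, axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            gg = reshape(g, (1,) * a.ndim)
        elif not keepdims:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            ax = tuple(x % a.ndim for x in ax)
            shp = tuple(1 if i in ax else s for i, s in enumerate(a.shape))
            gg = reshape(g, shp)
        else:
            gg = g
        return (mul(gg, Tensor(np.ones(a.shape, dtype=a.data.dtype))),)

    return _make(out_data, (a,), vjp)


def mean_(a, axis=None, keepdims=False):
    a = astensor(a)
    if axis is None:
        n = a.size
    else:
        ax = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[x % a.ndim] for x in ax]))
    return div(sum_(a, axis=axis, keepdims=keepdims), float(n))


def concatenate(tensors: Sequence, axis: int = 0):
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for i in range(len(tensors)):
            key = [slice(None)] * g.ndim
            key[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            outs.append(getitem(g, tuple(key)))
        return tuple(outs)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), vjp)


def pad2d(a, pad: int):
    """Zero-pad the trailing two axes symmetrically."""
    a = astensor(a)
    if pad == 0:
        return a
    width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
    key = tuple([slice(None)] * (a.ndim - 2)
                + [slice(pad, -pad), slice(pad, -pad)])
    return _make(np.pad(a.data, width), (a,), lambda g: (getitem(g, key),))


def getitem(a, key):
    a = astensor(a)
    shape = a.shape
    return _make(a.data[key], (a,),
                 lambda g: (scatter_slice(g, key, shape),))


def scatter_slice(g, key, shape):
    """Adjoint of basic-slice indexing: place g into zeros of `shape`."""
    g = astensor(g)
    out = np.zeros(shape, dtype=g.data.dtype)
    out[key] = g.data
    return _make(out, (g,), lambda gg: (getitem(gg, key),))


# ---------------------------------------------------------------------------
# patch gather/scatter — the im2col pair used by convolutions
# ---------------------------------------------------------------------------

def take_patches(a, idx: np.ndarray):
    """Gather flat indices per batch item: a is (B, M), idx int array;
    returns (B, *idx.shape).  Adjoint is :func:`put_patches`."""
    a = astensor(a)
    m = a.shape[1]
    return _make(a.data[:, idx], (a,),
                 lambda g: (put_patches(g, idx, m),))


def put_patches(g, idx: np.ndarray, m: int):
    """Scatter-add patches back: g is (B, *idx.shape) -> (B, m)."""
    g = astensor(g)
    b = g.shape[0]
    out = np.zeros((b, m), dtype=g.data.dtype)
    np.add.at(out, (np.arange(b)[:, None], idx.reshape(-1)[None, :]),
              g.data.reshape(b, -1))
    return _make(out, (g,), lambda gg: (take_patches(gg, idx),))


def dilate2d(a, factor: int):
    """Insert factor-1 zeros between pixels of the trailing two axes
    (the zero-stuffing step of a stride-`factor` transposed convolution)."""
    a = astensor(a)
    if factor == 1:
        return a
    h, w = a.shape[-2], a.shape[-1]
    shape = a.shape[:-2] + (h * factor, w * factor)
    key = tuple([slice(None)] * (a.ndim - 2)
                + [slice(None, None, factor), slice(None, None, factor)])
    return scatter_slice(a, key, shape)


# ---------------------------------------------------------------------------
# backward / grad
# ---------------------------------------------------------------------------

def _toposort(root: Tensor) -> list:
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order  # parents before children


def grad(out: Tensor, inputs: Sequence[Tensor],
         create_graph: bool = False) -> list:
    """Gradients of scalar `out` w.r.t. each tensor in `inputs`.

    With ``create_graph=True`` the returned tensors carry their own tape, so
    expressions of them can be differentiated again.
    """
    if out.size != 1:
        raise ValueError("grad expects a scalar output")
    grads: dict[int, Tensor] = {id(out): Tensor(np.ones(out.shape, dtype=out.data.dtype))}
    order = _toposort(out)
    wanted = {id(t) for t in inputs}

    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(order):
            g = grads.get(id(node))
            if g is None:
                continue
            if node.vjp is not None:
                parent_grads = node.vjp(g)
                for p, pg in zip(node.parents, parent_grads):
                    if not p.requires_grad:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = add(grads[id(p)], pg)
                    else:
                        grads[id(p)] = pg
            if id(node) not in wanted:
                del grads[id(node)]
    result = []
    for t in inputs:
        gt = grads.get(id(t))
        if gt is None:
            gt = Tensor(np.zeros(t.shape, dtype=t.data.dtype))
        result.append(gt)
    return result


def backward(out: Tensor, params: Sequence[Tensor]) -> list[np.ndarray]:
    """Plain (non-differentiable) gradient arrays for an optimizer step."""
    return [g.data for g in grad(out, params, create_graph=False)]
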