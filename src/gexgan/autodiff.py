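"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core the generator, critic, and baseline networks are
built on.  It supports higher-order gradients: every vector-Jacobian product
is itself expressed in terms of tracked tensor operations, so the gradient of
a gradient (as required by the WGAN gradient-penalty term, whose training
signal differentiates the critic's input gradient with respect to the critic
parameters) is obtained by calling :func:`grad` twice.

Only the operations the package's models need are implemented.  Shapes follow
numpy broadcasting; broadcasts are undone in the backward pass by summation.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph recording (cheap inference / sampling)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "requires_grad", "parents", "vjps")

    def __init__(self, data, requires_grad=False, parents=(), vjps=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.parents = parents
        self.vjps = vjps

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def __float__(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    @property
    def T(self):
        return swapaxes(self, -1, -2)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, vjps):
    if _GRAD_ENABLED and any(p is not None and p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=tuple(parents), vjps=tuple(vjps))
    return Tensor(data)


# ---------------------------------------------------------------------------
# broadcast bookkeeping


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.data.shape == tuple(shape):
        return g
    extra = g.data.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, (have, want) in enumerate(zip(g.data.shape, shape)) if want == 1 and have != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.data.shape != tuple(shape):
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# primitive operations


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data + b.data,
        (a, b),
        (lambda g: _unbroadcast(g, a.shape), lambda g: _unbroadcast(g, b.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data * b.data,
        (a, b),
        (lambda g: _unbroadcast(mul(g, b), a.shape), lambda g: _unbroadcast(mul(g, a), b.shape)),
    )


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    exponent = float(exponent)
    return _make(
        a.data ** exponent,
        (a,),
        (lambda g: mul(g, mul(power(a, exponent - 1.0), exponent)),),
    )


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)
    out = _make(out_data, (a,), ())
    if out.requires_grad:
        out.vjps = (lambda g: mul(g, out),)
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), (a,), (lambda g: mul(g, power(a, -1.0)),))


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data @ b.data,
        (a, b),
        (
            lambda g: _unbroadcast(matmul(g, swapaxes(b, -1, -2)), a.shape),
            lambda g: _unbroadcast(matmul(swapaxes(a, -1, -2), g), b.shape),
        ),
    )


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * a.ndim), a.shape)
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            kshape = list(a.shape)
            for ax in axes:
                kshape[ax] = 1
            g = reshape(g, tuple(kshape))
        return broadcast_to(g, a.shape)

    return _make(data, (a,), (vjp,))


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        count = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / count)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return _make(a.data.reshape(shape), (a,), (lambda g: reshape(g, a.shape),))


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    return _make(np.broadcast_to(a.data, shape).copy(), (a,), (lambda g: _unbroadcast(g, a.shape),))


def swapaxes(a, ax1, ax2) -> Tensor:
    a = as_tensor(a)
    return _make(np.swapaxes(a.data, ax1, ax2), (a,), (lambda g: swapaxes(g, ax1, ax2),))


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        lo, hi = offsets[i], offsets[i + 1]

        def vjp(g):
            index = [slice(None)] * g.ndim
            index[axis] = slice(lo, hi)
            return getitem(g, tuple(index))

        return vjp

    return _make(data, tuple(tensors), tuple(make_vjp(i) for i in range(len(tensors))))


def getitem(a, index) -> Tensor:
    a = as_tensor(a)

    def vjp(g):
        return _Scatter(a.shape, index)(g)

    return _make(a.data[index], (a,), (vjp,))


class _Scatter:
    """Adjoint of basic slicing: place the cotangent into a zero array."""

    def __init__(self, shape, index):
        self.shape, self.index = shape, index

    def __call__(self, g: Tensor) -> Tensor:
        shape, index = self.shape, self.index

        def vjp(gg):
            return getitem(gg, index)

        data = np.zeros(shape)
        np.add.at(data, index, g.data)
        return _make(data, (g,), (vjp,))


def take_rows(table, idx) -> Tensor:
    """Row lookup ``table[idx]`` (embedding gather); ``idx`` is an int array."""
    table = as_tensor(table)
    idx = np.asarray(idx, dtype=np.intp)
    return _make(table.data[idx], (table,), (lambda g: _Scatter(table.shape, idx)(g),))


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    scale = np.where(a.data > 0, 1.0, slope)
    return _make(a.data * scale, (a,), (lambda g: mul(g, Tensor(scale)),))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(out_data, (a,), ())
    if out.requires_grad:
        out.vjps = (lambda g: mul(g, mul(out, add(1.0, -out))),)
    return out


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)
    out = _make(out_data, (a,), ())
    if out.requires_grad:
        out.vjps = (lambda g: mul(g, add(1.0, -mul(out, out))),)
    return out


def softplus(a) -> Tensor:
    """Numerically stable log(1 + exp(a)); derivative is sigmoid(a)."""
    a = as_tensor(a)
    data = np.maximum(a.data, 0.0) + np.log1p(np.exp(-np.abs(a.data)))
    return _make(data, (a,), (lambda g: mul(g, sigmoid(a)),))


def node_mix(S: np.ndarray, h: Tensor) -> Tensor:
    """Apply a constant node-mixing matrix along the gene axis.

    ``S`` is an (n, n) array (dense or scipy sparse); ``h`` has shape
    (batch, n, features) or (n, features).  Returns S @ h per batch element.
    The adjoint applies S.T, so the op is closed under differentiation.
    """
    h = as_tensor(h)
    ST = S.T

    def apply(mat, arr):
        if arr.ndim == 2:
            return mat @ arr
        b, n, f = arr.shape
        flat = arr.transpose(1, 0, 2).reshape(n, b * f)
        out = mat @ flat
        return np.asarray(out).reshape(n, b, f).transpose(1, 0, 2)

    def vjp(g):
        return _make(apply(ST, g.data), (g,), (lambda gg: node_mix(S, gg),))

    return _make(apply(S, h.data), (h,), (vjp,))


# ---------------------------------------------------------------------------
# reverse pass


def _topo(root: Tensor):
    order, visited, stack = [], set(), [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p is not None and p.requires_grad and id(p) not in visited:
                stack.append((p, False))
    return order


def grad(output: Tensor, wrt, out_grad: Tensor | None = None):
    """Gradients of ``output`` with respect to each tensor in ``wrt``.

    The returned tensors are part of the computation graph, so a further
    :func:`grad` call through them yields second-order derivatives.
    """
    if not output.requires_grad:
        return [Tensor(np.zeros(w.shape)) for w in wrt]
    seed = out_grad if out_grad is not None else Tensor(np.ones(output.shape))
    order = _topo(output)
    cotangents: dict[int, Tensor] = {id(output): seed}
    keepalive = {id(t): t for t in order}
    for node in reversed(order):
        g = cotangents.get(id(node))
        if g is None:
            continue
        for parent, vjp in zip(node.parents, node.vjps):
            if parent is None or not parent.requires_grad:
                continue
            contribution = vjp(g)
            prev = cotangents.get(id(parent))
            cotangents[id(parent)] = contribution if prev is None else add(prev, contribution)
            keepalive[id(parent)] = parent
    return [cotangents.get(id(w), Tensor(np.zeros(w.shape))) for w in wrt]
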