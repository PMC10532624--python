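"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine sufficient for training the dense ResNets used
throughout the package.  Every operation is exposed as a module-level
function that accepts either plain ``numpy`` arrays or :class:`Var` nodes;
when no argument is a :class:`Var` the result is a plain array, so the same
network code runs in a fast pure-numpy mode for inference/sampling and in a
traced mode for training.

Also hosts the pytree helpers (nested dicts/lists of arrays) used for
parameter storage and the optimizer.
"""

from __future__ import annotations

from typing import Any, Callable

import numpy as np
from scipy.special import expit

__all__ = [
    "Var",
    "value",
    "backward",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "matmul",
    "power",
    "exp",
    "log",
    "sqrt",
    "square",
    "sin",
    "cos",
    "sigmoid",
    "softplus",
    "swish",
    "reduce_sum",
    "reduce_mean",
    "reshape",
    "concat",
    "getitem",
    "tree_map",
    "tree_leaves",
    "tree_flatten",
    "tree_unflatten",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    grad = np.asarray(grad, dtype=float)
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Var:
    """A node in the computation graph: a value plus how to propagate a gradient."""

    __slots__ = ("value", "grad", "_parents", "_vjps")

    def __init__(self, value, parents=(), vjps=()):
        self.value = np.asarray(value, dtype=float)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._vjps = vjps

    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    # arithmetic sugar ----------------------------------------------------
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

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Var(shape={self.value.shape})"


def value(x) -> np.ndarray:
    """Underlying array of ``x`` whether it is a Var or a plain array."""
    return x.value if isinstance(x, Var) else np.asarray(x, dtype=float)


def _node(val: np.ndarray, pairs) -> Var | np.ndarray:
    pairs = [(p, f) for p, f in pairs if isinstance(p, Var)]
    if not pairs:
        return val
    return Var(val, parents=tuple(p for p, _ in pairs), vjps=tuple(f for _, f in pairs))


def backward(out: Var) -> None:
    """Accumulate gradients of ``out`` (seeded with ones) into every ancestor's ``.grad``."""
    if not isinstance(out, Var):
        raise TypeError("backward() expects a Var")
    topo: list[Var] = []
    seen: set[int] = set()
    stack: list[tuple[Var, bool]] = [(out, False)]
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
    for node in topo:
        node.grad = None
    out.grad = np.ones_like(out.value)
    for node in reversed(topo):
        g = node.grad
        if g is None:
            continue
        for parent, vjp in zip(node._parents, node._vjps):
            pg = vjp(g)
            parent.grad = pg if parent.grad is None else parent.grad + pg


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------


def add(a, b):
    av, bv = value(a), value(b)
    return _node(av + bv, [
        (a, lambda g: _unbroadcast(g, av.shape)),
        (b, lambda g: _unbroadcast(g, bv.shape)),
    ])


def sub(a, b):
    av, bv = value(a), value(b)
    return _node(av - bv, [
        (a, lambda g: _unbroadcast(g, av.shape)),
        (b, lambda g: _unbroadcast(-g, bv.shape)),
    ])


def mul(a, b):
    av, bv = value(a), value(b)
    return _node(av * bv, [
        (a, lambda g: _unbroadcast(g * bv, av.shape)),
        (b, lambda g: _unbroadcast(g * av, bv.shape)),
    ])


def div(a, b):
    av, bv = value(a), value(b)
    return _node(av / bv, [
        (a, lambda g: _unbroadcast(g / bv, av.shape)),
        (b, lambda g: _unbroadcast(-g * av / (bv * bv), bv.shape)),
    ])


def neg(a):
    av = value(a)
    return _node(-av, [(a, lambda g: -g)])


def matmul(a, b):
    av, bv = value(a), value(b)
    out = av @ bv
    return _node(out, [
        (a, lambda g: g @ bv.T),
        (b, lambda g: av.T @ g),
    ])


def power(a, p: float):
    av = value(a)
    out = av ** p
    return _node(out, [(a, lambda g: g * p * av ** (p - 1))])


def exp(a):
    out = np.exp(value(a))
    return _node(out, [(a, lambda g: g * out)])


def log(a):
    av = value(a)
    return _node(np.log(av), [(a, lambda g: g / av)])


def sqrt(a):
    out = np.sqrt(value(a))
    return _node(out, [(a, lambda g: g * 0.5 / out)])


def square(a):
    return power(a, 2.0)


def sin(a):
    av = value(a)
    return _node(np.sin(av), [(a, lambda g: g * np.cos(av))])


def cos(a):
    av = value(a)
    return _node(np.cos(av), [(a, lambda g: -g * np.sin(av))])


def sigmoid(a):
    out = expit(value(a))
    return _node(out, [(a, lambda g: g * out * (1.0 - out))])


def softplus(a):
    av = value(a)
    out = np.logaddexp(0.0, av)
    return _node(out, [(a, lambda g: g * expit(av))])


def swish(a):
    """x * sigmoid(x), the SiLU activation."""
    return mul(a, sigmoid(a))


def reduce_sum(a, axis=None, keepdims=False):
    av = value(a)
    out = av.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        g = np.asarray(g, dtype=float)
        if axis is None:
            return np.broadcast_to(g, av.shape).copy()
        if not keepdims:
            g = np.expand_dims(g, axis=axis)
        return np.broadcast_to(g, av.shape).copy()

    return _node(out, [(a, vjp)])


def reduce_mean(a, axis=None, keepdims=False):
    av = value(a)
    n = av.size if axis is None else np.prod(
        [av.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return div(reduce_sum(a, axis=axis, keepdims=keepdims), float(n))


def reshape(a, shape):
    av = value(a)
    return _node(av.reshape(shape), [(a, lambda g: g.reshape(av.shape))])


def concat(parts, axis=-1):
    vals = [value(p) for p in parts]
    out = np.concatenate(vals, axis=axis)
    sizes = [v.shape[axis] for v in vals]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]

        return vjp

    return _node(out, [(p, make_vjp(i)) for i, p in enumerate(parts)])


def getitem(a, idx):
    av = value(a)
    out = av[idx]

    def vjp(g):
        full = np.zeros_like(av)
        np.add.at(full, idx, g)
        return full

    return _node(out, [(a, vjp)])


# ---------------------------------------------------------------------------
# pytrees: nested dicts / lists of arrays, used for network parameters
# ---------------------------------------------------------------------------


def tree_map(fn: Callable, *trees):
    t0 = trees[0]
    if isinstance(t0, dict):
        return {k: tree_map(fn, *[t[k] for t in trees]) for k in t0}
    if isinstance(t0, (list, tuple)):
        mapped = [tree_map(fn, *[t[i] for t in trees]) for i in range(len(t0))]
        return type(t0)(mapped)
    return fn(*trees)


def tree_leaves(tree) -> list:
    out: list = []

    def walk(t):
        if isinstance(t, dict):
            for k in sorted(t):
                walk(t[k])
        elif isinstance(t, (list, tuple)):
            for item in t:
                walk(item)
        else:
            out.append(t)

    walk(tree)
    return out


def tree_flatten(tree, prefix: str = "") -> dict[str, Any]:
    """Flatten a pytree into ``{"path/to/leaf": leaf}`` with sorted, stable paths."""
    flat: dict[str, Any] = {}

    def walk(t, path):
        if isinstance(t, dict):
            for k in sorted(t):
                walk(t[k], f"{path}/{k}" if path else str(k))
        elif isinstance(t, (list, tuple)):
            for i, item in enumerate(t):
                walk(item, f"{path}/{i}" if path else str(i))
        else:
            flat[path] = t

    walk(tree, prefix)
    return flat


def tree_unflatten(flat: dict[str, Any]):
    """Inverse of :func:`tree_flatten`; numeric path components become list indices."""
    root: dict = {}
    for path, leaf in flat.items():
        parts = path.split("/")
        node = root
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = leaf

    def finalize(node):
        if not isinstance(node, dict):
            return node
        keys = list(node.keys())
        if keys and all(k.isdigit() for k in keys):
            return [finalize(node[str(i)]) for i in range(len(keys))]
        return {k: finalize(v) for k, v in node.items()}

    return finalize(root)
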