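"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module provides exactly the primitives the spatial-temporal graph
pipeline needs — broadcast arithmetic, ``einsum``, element-wise
nonlinearities, row softmax, slicing/padding, and a gradient-reversal
node for domain-adversarial training — in a few hundred lines of numpy.
Every operation records a vector-Jacobian product; :meth:`Tensor.backward`
accumulates gradients in reverse topological order.

All values are float64.  The engine is deliberately eager and
single-threaded: determinism is a feature, not an optimisation target.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "parameter",
    "add",
    "mul",
    "matmul",
    "einsum",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "absolute",
    "sqrt",
    "power",
    "tensor_sum",
    "mean",
    "reshape",
    "transpose",
    "softmax",
    "log_softmax",
    "clamp",
    "pad",
    "concatenate",
    "grad_reverse",
    "detach",
    "RMSprop",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff.

    Parameters created with ``requires_grad=True`` accumulate into
    ``.grad`` when :meth:`backward` is called on a downstream scalar.
    """

    __slots__ = ("value", "grad", "requires_grad", "_vjps")

    def __init__(self, value, requires_grad: bool = False, _vjps: Sequence = ()):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        # keep only differentiable parents; constants prune the graph
        self._vjps: tuple = tuple((p, fn) for p, fn in _vjps if p.requires_grad)
        self.requires_grad = bool(requires_grad) or bool(self._vjps)

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def backward(self, grad=None) -> None:
        """Backpropagate ``grad`` (default: ones) from this tensor."""
        if grad is None:
            grad = np.ones_like(self.value)
        grad = np.asarray(grad, dtype=np.float64)

        # iterative topological sort (DFS, post-order)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._vjps:
                if id(parent) not in seen:
                    stack.append((parent, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._vjps:
                node.grad = g if node.grad is None else node.grad + g
            for parent, fn in node._vjps:
                pg = fn(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = np.asarray(pg, dtype=np.float64)

    # ------------------------------------------------------------------
    # operator sugar
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(tensor(other), -1.0))

    def __rsub__(self, other):
        return add(tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        return mul(self, power(tensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(tensor(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return _getitem(self, idx)


# ----------------------------------------------------------------------
def tensor(x) -> Tensor:
    """Wrap ``x`` in a constant :class:`Tensor` (no-op if already one)."""
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(x) -> Tensor:
    """A leaf tensor that accumulates gradients."""
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


def detach(t: Tensor) -> Tensor:
    """Cut the graph: same value, no gradient flow."""
    return Tensor(tensor(t).value)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ----------------------------------------------------------------------
def add(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    return Tensor(
        a.value + b.value,
        _vjps=[
            (a, lambda g: _unbroadcast(g, a.value.shape)),
            (b, lambda g: _unbroadcast(g, b.value.shape)),
        ],
    )


def mul(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    return Tensor(
        a.value * b.value,
        _vjps=[
            (a, lambda g: _unbroadcast(g * b.value, a.value.shape)),
            (b, lambda g: _unbroadcast(g * a.value, b.value.shape)),
        ],
    )


def matmul(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)

    def grad_a(g):
        return _unbroadcast(np.matmul(g, np.swapaxes(b.value, -1, -2)), a.value.shape)

    def grad_b(g):
        return _unbroadcast(np.matmul(np.swapaxes(a.value, -1, -2), g), b.value.shape)

    return Tensor(np.matmul(a.value, b.value), _vjps=[(a, grad_a), (b, grad_b)])


def einsum(spec: str, *operands) -> Tensor:
    """Differentiable ``np.einsum``.

    Restriction: every index of an operand must also appear in the output
    or in another operand (no within-operand sums/traces), which holds for
    all contractions used in this package.
    """
    ts = [tensor(t) for t in operands]
    in_part, out_spec = spec.replace(" ", "").split("->")
    in_specs = in_part.split(",")
    value = np.einsum(spec, *[t.value for t in ts])

    vjps = []
    for i, t in enumerate(ts):
        def fn(g, i=i):
            subs = [out_spec] + [s for j, s in enumerate(in_specs) if j != i]
            ops = [g] + [u.value for j, u in enumerate(ts) if j != i]
            return np.einsum(",".join(subs) + "->" + in_specs[i], *ops)

        vjps.append((t, fn))
    return Tensor(value, _vjps=vjps)


def relu(a) -> Tensor:
    a = tensor(a)
    mask = a.value > 0
    return Tensor(np.where(mask, a.value, 0.0), _vjps=[(a, lambda g: g * mask)])


def sigmoid(a) -> Tensor:
    a = tensor(a)
    # numerically stable logistic
    y = np.where(a.value >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.value))),
                 np.exp(-np.abs(a.value)) / (1.0 + np.exp(-np.abs(a.value))))
    return Tensor(y, _vjps=[(a, lambda g: g * y * (1.0 - y))])


def exp(a) -> Tensor:
    a = tensor(a)
    y = np.exp(a.value)
    return Tensor(y, _vjps=[(a, lambda g: g * y)])


def log(a) -> Tensor:
    a = tensor(a)
    return Tensor(np.log(a.value), _vjps=[(a, lambda g: g / a.value)])


def absolute(a) -> Tensor:
    a = tensor(a)
    return Tensor(np.abs(a.value), _vjps=[(a, lambda g: g * np.sign(a.value))])


def sqrt(a) -> Tensor:
    a = tensor(a)
    y = np.sqrt(a.value)
    return Tensor(y, _vjps=[(a, lambda g: g * 0.5 / y)])


def power(a, p: float) -> Tensor:
    a = tensor(a)
    y = a.value ** p
    return Tensor(y, _vjps=[(a, lambda g: g * p * a.value ** (p - 1.0))])


def tensor_sum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = tensor(a)
    value = a.value.sum(axis=axis, keepdims=keepdims)

    def fn(g):
        if axis is None:
            return np.broadcast_to(g, a.value.shape).copy()
        if not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, a.value.shape).copy()

    return Tensor(value, _vjps=[(a, fn)])


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = tensor(a)
    n = a.value.size if axis is None else a.value.shape[axis]
    return mul(tensor_sum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = tensor(a)
    return Tensor(a.value.reshape(shape), _vjps=[(a, lambda g: g.reshape(a.value.shape))])


def transpose(a, axes) -> Tensor:
    a = tensor(a)
    inverse = np.argsort(axes)
    return Tensor(a.value.transpose(axes), _vjps=[(a, lambda g: g.transpose(inverse))])


def softmax(a, axis: int = -1) -> Tensor:
    """Row-stochastic softmax with max-subtraction for stability."""
    a = tensor(a)
    shifted = a.value - a.value.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def fn(g):
        return (g - (g * y).sum(axis=axis, keepdims=True)) * y

    return Tensor(y, _vjps=[(a, fn)])


def log_softmax(a, axis: int = -1) -> Tensor:
    a = tensor(a)
    shifted = a.value - a.value.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    y = shifted - lse
    sm = np.exp(y)

    def fn(g):
        return g - sm * g.sum(axis=axis, keepdims=True)

    return Tensor(y, _vjps=[(a, fn)])


def clamp(a, lo: float, hi: float) -> Tensor:
    """Clip values; gradient passes through only where un-clipped."""
    a = tensor(a)
    mask = (a.value >= lo) & (a.value <= hi)
    return Tensor(np.clip(a.value, lo, hi), _vjps=[(a, lambda g: g * mask)])


def pad(a, pad_width) -> Tensor:
    """Zero-pad; ``pad_width`` as for ``np.pad``."""
    a = tensor(a)
    pw = [(int(lo), int(hi)) for lo, hi in pad_width]
    slices = tuple(slice(lo, lo + s) for (lo, _), s in zip(pw, a.value.shape))
    return Tensor(np.pad(a.value, pw), _vjps=[(a, lambda g: g[slices])])


def _getitem(a: Tensor, idx) -> Tensor:
    a = tensor(a)

    def fn(g):
        out = np.zeros_like(a.value)
        out[idx] = g
        return out

    return Tensor(a.value[idx], _vjps=[(a, fn)])


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [tensor(t) for t in tensors]
    value = np.concatenate([t.value for t in ts], axis=axis)
    sizes = [t.value.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    vjps = []
    for i, t in enumerate(ts):
        def fn(g, i=i):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return g[tuple(sl)]

        vjps.append((t, fn))
    return Tensor(value, _vjps=vjps)


def grad_reverse(a, lam: float) -> Tensor:
    """Identity in the forward pass; multiplies the gradient by ``-lam``.

    The gradient-reversal contract that turns a domain-discriminator
    minimisation into an adversarial maximisation for everything upstream.
    """
    a = tensor(a)
    return Tensor(a.value.copy(), _vjps=[(a, lambda g: -lam * g)])


# ----------------------------------------------------------------------
class RMSprop:
    """RMSprop over a list of parameter tensors.

    v <- alpha*v + (1-alpha)*g^2 ;  p <- p - lr * g / (sqrt(v) + eps)
    """

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 alpha: float = 0.99, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.alpha = float(alpha)
        self.eps = float(eps)
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            if p.grad is None:
                continue
            v *= self.alpha
            v += (1.0 - self.alpha) * p.grad ** 2
            p.value -= self.lr * p.grad / (np.sqrt(v) + self.eps)
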