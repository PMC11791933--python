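"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A tape-free, graph-walking engine in the micrograd style, sized for the tiny
transformer encoders in this package.  Every :class:`Tensor` wraps an ndarray;
operations build a DAG of parents and local vector-Jacobian products, and
:meth:`Tensor.backward` runs a topological sweep accumulating gradients.

Only leaf tensors with ``requires_grad=True`` receive a ``.grad`` after
backward; frozen parameters (``requires_grad=False``) are guaranteed to end
with ``grad is None``, which is how the tuning toolbox expresses "this weight
receives exactly zero gradient".

Broadcasting follows NumPy semantics; gradients of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "embedding_lookup",
    "relu",
    "gelu",
    "logsumexp",
    "softmax",
    "SGD",
    "Adam",
    "clip_grad_norm",
]


def _as_array(x, dtype=None) -> np.ndarray:
    a = np.asarray(x)
    if dtype is not None and a.dtype != dtype:
        a = a.astype(dtype)
    elif a.dtype.kind in "iub":
        a = a.astype(np.float64)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data: np.ndarray = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjp: Callable[[np.ndarray], tuple] | None = None

    # -- graph construction -------------------------------------------------

    @classmethod
    def _from_op(cls, data: np.ndarray, parents: Sequence["Tensor"],
                 vjp: Callable[[np.ndarray], tuple]) -> "Tensor":
        out = cls.__new__(cls)
        out.data = data
        out.grad = None
        out.requires_grad = False
        out._parents = tuple(parents)
        out._vjp = vjp
        return out

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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'None'})"

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data
        return Tensor._from_op(
            a + b, (self, other),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data
        return Tensor._from_op(
            a * b, (self, other),
            lambda g: (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data
        return Tensor._from_op(
            a / b, (self, other),
            lambda g: (_unbroadcast(g / b, a.shape),
                       _unbroadcast(-g * a / (b * b), b.shape)))

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        a = self.data
        return Tensor._from_op(
            a ** p, (self,), lambda g: (g * p * a ** (p - 1),))

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self.data, other.data
        out = a @ b

        def vjp(g):
            if b.ndim == 1:
                ga = np.outer(g, b) if a.ndim > 1 else g * b
                gb = a.T @ g if a.ndim > 1 else g * a
            elif a.ndim == 1:
                ga = g @ b.swapaxes(-1, -2)
                gb = np.outer(a, g)
            else:
                ga = _unbroadcast(g @ b.swapaxes(-1, -2), a.shape)
                gb = _unbroadcast(a.swapaxes(-1, -2) @ g, b.shape)
            return ga, gb

        return Tensor._from_op(out, (self, other), vjp)

    # -- elementwise nonlinearities -----------------------------------------

    def exp(self):
        out = np.exp(self.data)
        return Tensor._from_op(out, (self,), lambda g: (g * out,))

    def log(self):
        a = self.data
        return Tensor._from_op(np.log(a), (self,), lambda g: (g / a,))

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._from_op(out, (self,), lambda g: (g * (1.0 - out * out),))

    # -- reductions and reshaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self.data

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, a.shape).copy(),)

        return Tensor._from_op(a.sum(axis=axis, keepdims=keepdims), (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        a = self.data
        n = a.size if axis is None else (
            math.prod(a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self.data
        return Tensor._from_op(
            a.reshape(shape), (self,), lambda g: (g.reshape(a.shape),))

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)
        return Tensor._from_op(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),))

    def swapaxes(self, a1: int, a2: int):
        return Tensor._from_op(
            self.data.swapaxes(a1, a2), (self,), lambda g: (g.swapaxes(a1, a2),))

    def __getitem__(self, idx):
        a = self.data
        out = a[idx]

        def vjp(g):
            ga = np.zeros_like(a)
            np.add.at(ga, idx, g)
            return (ga,)

        return Tensor._from_op(out, (self,), vjp)

    # -- backward -----------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = _as_array(grad)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                if node._vjp is not None:  # unused branch: free eagerly
                    node._vjp = None
                    node._parents = ()
                continue
            if node._vjp is None:
                if node.requires_grad:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
            # single-shot backward: release the closure and parent links so
            # intermediate arrays are freed as the sweep walks down the graph
            node._vjp = None
            node._parents = ()


class Parameter(Tensor):
    """A leaf tensor that an optimizer may update; freeze via ``requires_grad``."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# -- free functions ---------------------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    arrays = [t.data for t in tensors]
    sizes = [a.shape[axis] for a in arrays]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(arrays)))

    return Tensor._from_op(np.concatenate(arrays, axis=axis), tensors, vjp)


def embedding_lookup(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)
    return weight[ids]


def relu(x: Tensor) -> Tensor:
    a = x.data
    mask = a > 0
    return Tensor._from_op(np.where(mask, a, 0.0), (x,), lambda g: (g * mask,))


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = x.data
    cdf = 0.5 * (1.0 + _erf(a / math.sqrt(2.0)))
    pdf = np.exp(-0.5 * a * a) / math.sqrt(2.0 * math.pi)
    return Tensor._from_op(a * cdf, (x,), lambda g: (g * (cdf + a * pdf),))


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp via detached max subtraction."""
    m = np.max(x.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    shifted = x - Tensor(m)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims:
        out = out.reshape(tuple(s for i, s in enumerate(x.shape) if i != (axis % x.ndim)))
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    e = (x - Tensor(m)).exp()
    return e / e.sum(axis=axis, keepdims=True)


# -- optimizers -------------------------------------------------------------


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay."""

    def __init__(self, params: Iterable[Parameter], lr: float,
                 momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1t = 1.0 - self.b1 ** self._t
        b2t = 1.0 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def clip_grad_norm(params: Iterable[Parameter], max_norm: float) -> float:
    """Scale gradients in-place so their global L2 norm is at most ``max_norm``.

    Returns the pre-clip norm.
    """
    params = [p for p in params if p.grad is not None]
    total = math.sqrt(sum(float(np.sum(p.grad * p.grad)) for p in params))
    if total > max_norm and total > 0.0:
        scale = max_norm / total
        for p in params:
            p.grad = p.grad * scale
    return total
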