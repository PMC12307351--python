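"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains small transformer encoders, a bidirectional cross-modal
attention block and an attention-reduced classification head end to end.  All
of that needs gradients of a composite objective (temperature-scaled
contrastive loss, cosine alignment loss, binary cross-entropy) with respect to
every weight matrix.  This module provides exactly the primitives those models
use — broadcast-aware arithmetic, batched matmul, softmax / log-sum-exp with
the usual max-subtraction stabilisation, reductions, reshapes, row gathers —
as a :class:`Tensor` graph with a topological backward pass, plus a decoupled
weight-decay Adam optimiser.

Design notes
------------
* Arrays are float64 throughout; at the model sizes used here the cost is
  negligible and double precision keeps finite-difference checks tight.
* Gradients for broadcast operands are reduced back to the operand's shape
  (`_unbroadcast`), so biases and scalar constants compose freely.
* ``softmax``/``logsumexp`` are primitives with closed-form vector-Jacobian
  products rather than compositions, both for speed and so that the stabilised
  forms are what the graph differentiates.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "AdamW", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse added leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> np.ndarray:
        return self.data

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bwd(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bwd(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1.0),)
        return out

    def sqrt(self):
        return self.pow(0.5)

    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))
        out._backward = lambda g: (g * out.data,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))
        out._backward = lambda g: (g * (self.data > 0.0),)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), self.requires_grad, (self,))
        out._backward = lambda g: (g * (1.0 - out.data ** 2),)
        return out

    # --------------------------------------------------------- linear algebra
    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bwd(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                # (..., n) @ (n,) -> (...,)
                ga = g[..., None] * b
                gb = _unbroadcast((a * g[..., None]).reshape(-1, b.shape[0]).sum(0), b.shape)
            elif a.ndim == 1:
                ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
                gb = _unbroadcast(np.einsum("i,...j->...ij", a, g), b.shape)
            else:
                ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
                gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return ga, gb

        out._backward = bwd
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda g: (g.transpose(inv),)
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))
        out._backward = lambda g: (np.swapaxes(g, a, b),)
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = bwd
        return out

    def take_rows(self, indices: np.ndarray):
        """Gather rows of a 2-D table; `indices` may have any shape."""
        idx = np.asarray(indices)
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = bwd
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.data.shape).copy(),)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1, additive_mask: np.ndarray | None = None):
        """Stabilised softmax; `additive_mask` is a constant added to logits."""
        z = self.data if additive_mask is None else self.data + additive_mask
        z = z - z.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(p, self.requires_grad, (self,))

        def bwd(g):
            inner = (g * p).sum(axis=axis, keepdims=True)
            return (p * (g - inner),)

        out._backward = bwd
        return out

    def logsumexp(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        s = np.exp(self.data - m).sum(axis=axis, keepdims=True)
        val = (m + np.log(s)).squeeze(axis)
        out = Tensor(val, self.requires_grad, (self,))

        def bwd(g):
            soft = np.exp(self.data - m) / s
            return (np.expand_dims(g, axis) * soft,)

        out._backward = bwd
        return out

    # ---------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS (graphs can be deep for stacked layers)
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                stack.pop()
                if node.requires_grad:
                    topo.append(node)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if isinstance(node, Parameter) or node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for parent, pg in zip(node._parents, parent_grads):
                if not parent.requires_grad or pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
            if node._parents == ():
                node.grad = g if node.grad is None else node.grad + g


class Parameter(Tensor):
    """A trainable leaf tensor. ``frozen`` excludes it from optimiser updates."""

    __slots__ = ("frozen", "name")

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True)
        self.frozen = False
        self.name = name


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = bwd
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )

    def bwd(g):
        return tuple(np.moveaxis(g, axis, 0))

    out._backward = bwd
    return out


class AdamW:
    """Adam with decoupled weight decay over a list of :class:`Parameter`.

    Frozen parameters are skipped entirely, so their values stay bit-identical
    across any number of steps (the freeze-policy contract relies on this).
    """

    def __init__(self, params, lr: float = 1e-5, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-5):
        self.params = [p for p in params if isinstance(p, Parameter)]
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = {id(p): np.zeros_like(p.data) for p in self.params}
        self._v = {id(p): np.zeros_like(p.data) for p in self.params}

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p in self.params:
            if p.frozen or p.grad is None:
                continue
            m = self._m[id(p)]
            v = self._v[id(p)]
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            mhat = m / (1.0 - self.b1 ** self.t)
            vhat = v / (1.0 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)
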