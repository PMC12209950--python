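"""Minimal reverse-mode automatic differentiation on dense numpy arrays.

The message-passing layers in :mod:`moimech.gnn` operate on graphs with at
most a few hundred nodes, so every operation here is dense.  The engine
supports exactly the primitives those layers, the multi-label training loop
and integrated gradients need: broadcast arithmetic, matrix products, the
ReLU/LeakyReLU/sigmoid nonlinearities, axis reductions, row selection and a
numerically stable binary-cross-entropy-with-logits loss.

Gradients accumulate into ``Tensor.grad`` when :meth:`Tensor.backward` is
called on a scalar result.  There is no graph retention or higher-order
differentiation; each forward pass builds a fresh tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "relu", "leaky_relu", "sigmoid", "exp", "log", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, n in enumerate(shape):
        if n == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._from_op(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._from_op(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._from_op(data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._from_op(data, (self, other), backward)

    # -- reductions / reshaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        data = self.data.reshape(*shape)

        def backward(g):
            return (g.reshape(self.shape),)

        return Tensor._from_op(data, (self,), backward)

    def take_rows(self, idx):
        """Select rows; gradients scatter-add back."""
        idx = np.asarray(idx, dtype=np.intp)
        data = self.data[idx]

        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._from_op(data, (self,), backward)

    # -- tape -----------------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg
        # leaves with tape entries but also requiring grads were handled above


def relu(t: Tensor) -> Tensor:
    mask = t.data > 0
    return Tensor._from_op(t.data * mask, (t,), lambda g: (g * mask,))


def leaky_relu(t: Tensor, negative_slope: float = 0.2) -> Tensor:
    slope = np.where(t.data > 0, 1.0, negative_slope)
    return Tensor._from_op(t.data * slope, (t,), lambda g: (g * slope,))


def sigmoid(t: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(t.data, -500, 500)))
    return Tensor._from_op(s, (t,), lambda g: (g * s * (1.0 - s),))


def exp(t: Tensor) -> Tensor:
    e = np.exp(t.data)
    return Tensor._from_op(e, (t,), lambda g: (g * e,))


def log(t: Tensor) -> Tensor:
    return Tensor._from_op(np.log(t.data), (t,), lambda g: (g / t.data,))


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over all elements, computed from logits.

    Uses the log-sum-exp identity ``softplus(z) - y*z`` so the loss and its
    gradient ``(sigmoid(z) - y) / n`` stay finite for large |z|.
    """
    y = np.asarray(targets, dtype=np.float64)
    z = logits.data
    if z.shape != y.shape:
        raise ValueError(f"logits shape {z.shape} != targets shape {y.shape}")
    softplus = np.logaddexp(0.0, z)
    loss = float(np.mean(softplus - y * z))
    n = z.size
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def backward(g):
        return (g * (p - y) / n,)

    return Tensor._from_op(loss, (logits,), backward)
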