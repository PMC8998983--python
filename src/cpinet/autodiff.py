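"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps an
``ndarray`` and remembers how it was produced, and :meth:`Tensor.backward`
walks the tape in reverse topological order accumulating gradients into the
leaves that asked for them.  Only the operations the network layers need are
provided; all arrays are float64 so that seeded runs are bit-reproducible on
a single CPU.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[Array], Sequence[Array | None]] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ---- bookkeeping -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Array | None = None) -> None:
        if not self.requires_grad:
            raise ValueError("called backward on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        # topological order over the reachable graph
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf: accumulate
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g

    # ---- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, power(other, -1.0))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---- elementwise ---------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g: Array):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g: Array):
        return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

    return Tensor(out_data, parents=(a, b), backward=backward)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** exponent

    def backward(g: Array):
        return (g * exponent * a.data ** (exponent - 1.0),)

    return Tensor(out_data, parents=(a,), backward=backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g: Array):
        return (g * out_data,)

    return Tensor(out_data, parents=(a,), backward=backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.log(a.data)

    def backward(g: Array):
        return (g / a.data,)

    return Tensor(out_data, parents=(a,), backward=backward)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(g: Array):
        return (g * (1.0 - out_data * out_data),)

    return Tensor(out_data, parents=(a,), backward=backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g: Array):
        return (g * out_data * (1.0 - out_data),)

    return Tensor(out_data, parents=(a,), backward=backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0)

    def backward(g: Array):
        return (g * mask,)

    return Tensor(out_data, parents=(a,), backward=backward)


ACTIVATIONS: dict[str, Callable[[Tensor], Tensor]] = {
    "relu": relu,
    "tanh": tanh,
    "sigmoid": sigmoid,
    "identity": lambda t: t,
}


# ---- linear algebra ------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g: Array):
        ga = g @ b.data.T if a.requires_grad else None
        gb = a.data.T @ g if b.requires_grad else None
        return ga, gb

    return Tensor(out_data, parents=(a, b), backward=backward)


# ---- reductions ----------------------------------------------------------

def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g: Array):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        g_exp = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g_exp, a.shape).copy(),)

    return Tensor(out_data, parents=(a,), backward=backward)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def max_(a, axis: int) -> Tensor:
    """Max along one axis; gradient flows to the first argmax."""
    a = _as_tensor(a)
    out_data = a.data.max(axis=axis)
    argmax = a.data.argmax(axis=axis)

    def backward(g: Array):
        grad = np.zeros_like(a.data)
        idx = list(np.indices(out_data.shape))
        idx.insert(axis if axis >= 0 else a.data.ndim + axis, argmax)
        grad[tuple(idx)] = g
        return (grad,)

    return Tensor(out_data, parents=(a,), backward=backward)


# ---- shape / indexing ----------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g: Array):
        return (g.reshape(a.shape),)

    return Tensor(out_data, parents=(a,), backward=backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: Array):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out_data, parents=tuple(ts), backward=backward)


def take_rows(a, index: Array) -> Tensor:
    """Gather rows of a 2-D tensor by a constant integer index array.

    Serves both as embedding lookup (index = token ids) and as the shifted
    "im2col" gather for 1-D convolution; the gradient scatter-adds.
    """
    a = _as_tensor(a)
    index = np.asarray(index, dtype=np.intp)
    out_data = a.data[index]

    def backward(g: Array):
        grad = np.zeros_like(a.data)
        np.add.at(grad, index, g)
        return (grad,)

    return Tensor(out_data, parents=(a,), backward=backward)


def softmax(a, axis: int = -1, mask: Array | None = None) -> Tensor:
    """Numerically stable softmax; ``mask`` (0/1 constant) marks valid slots."""
    a = _as_tensor(a)
    logits = a
    if mask is not None:
        # push masked-out slots to a large negative value (constant offset)
        logits = add(a, Tensor((mask - 1.0) * 1e9))
    shift = Tensor(logits.data.max(axis=axis, keepdims=True))  # detached
    z = exp(add(logits, mul(shift, -1.0)))
    denom = sum_(z, axis=axis, keepdims=True)
    return mul(z, power(denom, -1.0))


def log_softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))  # detached
    shifted = add(a, mul(shift, -1.0))
    lse = log(sum_(exp(shifted), axis=axis, keepdims=True))
    return add(shifted, mul(lse, -1.0))
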