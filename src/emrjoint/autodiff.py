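"""Reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine in the micrograd style, generalized to tensors
with broadcasting. It provides exactly the primitives the joint model
needs: arithmetic, matrix multiplication, ReLU, exp/log/sqrt, reductions
(sum, max, logsumexp), fancy row gathering and concatenation. Gradients
are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`, which
performs a topological sweep over the recorded graph.

All computation is float64 for numerically tight gradient checks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "logsumexp", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # Sum over leading axes added by broadcasting.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # Sum over axes that were stretched from size 1.
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(grad, b.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(grad, a=self):
            if a.requires_grad:
                a._accumulate(-grad)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(grad * a.data, b.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(
                    _unbroadcast(-grad * a.data / (b.data**2), b.shape)
                )

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(grad @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ grad)

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(grad, a=self, mask=mask):
            if a.requires_grad:
                a._accumulate(grad * mask)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(grad, a=self, out_data=out_data):
            if a.requires_grad:
                a._accumulate(grad * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(grad, a=self):
            if a.requires_grad:
                a._accumulate(grad / a.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def backward(grad, a=self, out_data=out_data):
            if a.requires_grad:
                a._accumulate(grad / (2.0 * out_data))

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(grad, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._from_op(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(count)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        # Route gradient to the first argmax along the axis (deterministic).
        idx = self.data.argmax(axis=axis)

        def backward(grad, a=self, axis=axis, keepdims=keepdims, idx=idx):
            if not a.requires_grad:
                return
            g = grad if keepdims else np.expand_dims(grad, axis)
            full = np.zeros_like(a.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            a._accumulate(full)

        return Tensor._from_op(out_data, (self,), backward)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        def backward(grad, a=self):
            if a.requires_grad:
                a._accumulate(grad.reshape(a.shape))

        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    @property
    def T(self) -> "Tensor":
        def backward(grad, a=self):
            if a.requires_grad:
                a._accumulate(grad.T)

        return Tensor._from_op(self.data.T, (self,), backward)

    def take_rows(self, start: int, stop: int) -> "Tensor":
        """Differentiable contiguous row slice ``self[start:stop]``."""

        def backward(grad, a=self, start=start, stop=stop):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[start:stop] = grad
                a._accumulate(full)

        return Tensor._from_op(self.data[start:stop], (self,), backward)

    def __getitem__(self, key) -> "Tensor":
        """Differentiable indexing (scatter-add on the way back)."""

        def backward(grad, a=self, key=key):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, key, grad)
                a._accumulate(full)

        return Tensor._from_op(self.data[key], (self,), backward)

    # -- autodiff driver --------------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from a scalar output through the recorded graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad, tensors=tensors, splits=splits, axis=axis):
        pieces = np.split(grad, splits, axis=axis)
        for t, g in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(g)

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def logsumexp(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp; differentiable, -inf safe.

    Entries equal to -inf (used for forbidden CRF transitions) receive
    zero gradient.
    """
    x = as_tensor(x)
    m = np.max(x.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)  # all -inf row -> lse = -inf
    exp_shifted = np.exp(x.data - m)
    sums = exp_shifted.sum(axis=axis, keepdims=True)
    out_data = np.log(sums) + m
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def backward(grad, x=x, softmax_w=exp_shifted / sums, axis=axis,
                 keepdims=keepdims):
        if x.requires_grad:
            g = grad if keepdims else np.expand_dims(grad, axis)
            x._accumulate(g * softmax_w)

    return Tensor._from_op(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Row-stable softmax built from differentiable primitives."""
    x = as_tensor(x)
    return (x - logsumexp(x, axis=axis, keepdims=True)).exp()
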