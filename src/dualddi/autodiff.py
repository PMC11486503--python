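"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the model needs: broadcast arithmetic,
(batched) matrix products, ReLU, softplus, sqrt, reductions, reshaping,
concatenation and a numerically stable masked softmax.  Gradients follow the
usual tape construction: every op records its parents and a closure that
pushes the upstream gradient back to them; ``Tensor.backward`` walks the tape
in reverse topological order.

All data is float64.  Tensors are expected to be at least 2-D; 1-D arrays are
promoted on construction to keep matmul gradient rules uniform.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "masked_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        arr = np.asarray(data, dtype=np.float64)
        if arr.ndim == 0:
            arr = arr.reshape(1, 1)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- plumbing ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data / other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / (other.data ** 2))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        if a.ndim > 2 and b.ndim == 2:
            # (…, N, d) @ (d, k): one flattened gemm instead of a gemm per
            # batch element; numerically identical and much faster.
            lead = a.shape[:-1]
            a2 = a.reshape(-1, a.shape[-1])
            out = Tensor(
                (a2 @ b).reshape(*lead, b.shape[-1]),
                self.requires_grad or other.requires_grad,
                (self, other),
            )

            def backward(g):
                g2 = g.reshape(-1, g.shape[-1])
                if self.requires_grad:
                    self._accumulate((g2 @ b.T).reshape(a.shape))
                if other.requires_grad:
                    other._accumulate(a2.T @ g2)

            out._backward = backward
            return out
        out = Tensor(
            np.matmul(a, b),
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.matmul(g, b.swapaxes(-1, -2)))
            if other.requires_grad:
                other._accumulate(np.matmul(a.swapaxes(-1, -2), g))

        out._backward = backward
        return out

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        keep = self.data > 0
        out = Tensor(self.data * keep, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * keep)
        return out

    def softplus(self):
        out = Tensor(np.logaddexp(0.0, self.data), self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                sig = 1.0 / (1.0 + np.exp(-self.data))
                self._accumulate(g * sig)

        out._backward = backward
        return out

    def sqrt(self):
        root = np.sqrt(self.data)
        out = Tensor(root, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * 0.5 / np.maximum(root, 1e-300)
        )
        return out

    # -- reductions / reshaping --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.reshape(self.data.shape)
        )
        return out

    def swapaxes(self, ax1, ax2):
        out = Tensor(self.data.swapaxes(ax1, ax2), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.swapaxes(ax1, ax2)
        )
        return out

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = backward
    return out


def masked_softmax(logits: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Row softmax over the last axis, restricted to positions where mask==1.

    ``mask`` is a constant (non-differentiated) 0/1 array broadcastable to
    ``logits``; masked-out positions receive exactly zero weight.  Every row
    must contain at least one valid position.
    """
    x = logits.data
    if mask is not None:
        mask = np.broadcast_to(np.asarray(mask, dtype=np.float64), x.shape)
        if not np.all(mask.max(axis=-1) > 0):
            raise ValueError("masked_softmax: a row has no valid positions")
        x = np.where(mask > 0, x, -np.inf)
    shifted = x - x.max(axis=-1, keepdims=True)
    expx = np.exp(shifted)
    soft = expx / expx.sum(axis=-1, keepdims=True)
    out = Tensor(soft, logits.requires_grad, (logits,))

    def backward(g):
        if logits.requires_grad:
            inner = (g * soft).sum(axis=-1, keepdims=True)
            logits._accumulate(soft * (g - inner))

    out._backward = backward
    return out
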