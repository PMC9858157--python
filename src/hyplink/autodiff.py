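"""Compact reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the hyperlink-prediction model needs:
dense matrix products, elementwise nonlinearities, broadcasting adds,
row gathering, and segment reductions (the building blocks of softmax
attention over variable-size neighborhoods and hyperedges).

All arrays are float64.  Gradients are accumulated into ``Tensor.grad``
by :meth:`Tensor.backward`, which runs a topological sweep over the
recorded tape.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "segment_sum", "segment_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents: Sequence["Tensor"],
                 backward: Callable[[np.ndarray], None]) -> "Tensor":
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

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -g * self.data / (other.data ** 2), other.data.shape))

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                if other.data.ndim == 1:
                    self._accumulate(np.outer(g, other.data)
                                     if self.data.ndim == 2 else g * other.data)
                else:
                    self._accumulate(g @ other.data.T)
            if other.requires_grad:
                if self.data.ndim == 1:
                    other._accumulate(np.outer(self.data, g)
                                      if other.data.ndim == 2 else g * self.data)
                else:
                    other._accumulate(self.data.T @ g)

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    @property
    def T(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.T)

        return Tensor._from_op(self.data.T, (self,), backward)

    # -- nonlinearities -------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def leaky_relu(self, alpha: float = 0.2) -> "Tensor":
        slope = np.where(self.data > 0, 1.0, alpha)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * slope)

        return Tensor._from_op(self.data * slope, (self,), backward)

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * (1.0 - out ** 2))

        return Tensor._from_op(out, (self,), backward)

    def sigmoid(self) -> "Tensor":
        # stable for both signs
        out = np.where(self.data >= 0,
                       1.0 / (1.0 + np.exp(-np.abs(self.data))),
                       np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * out * (1.0 - out))

        return Tensor._from_op(out, (self,), backward)

    def softplus(self) -> "Tensor":
        # log(1 + exp(x)) = max(x, 0) + log1p(exp(-|x|))
        out = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = np.where(self.data >= 0,
                       1.0 / (1.0 + np.exp(-np.abs(self.data))),
                       np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * sig)

        return Tensor._from_op(out, (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values to [lo, hi]; gradient is zero where clipped."""
        inside = (self.data >= lo) & (self.data <= hi)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * inside)

        return Tensor._from_op(np.clip(self.data, lo, hi), (self,), backward)

    def exp(self) -> "Tensor":
        out = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * out)

        return Tensor._from_op(out, (self,), backward)

    # -- reductions & indexing ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims),
                               (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            count = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def gather(self, idx: np.ndarray) -> "Tensor":
        """Select rows (axis 0) by integer index, with repetition."""
        idx = np.asarray(idx, dtype=np.intp)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                out = np.zeros_like(self.data)
                np.add.at(out, idx, g)
                self._accumulate(out)

        return Tensor._from_op(self.data[idx], (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    # -- backward pass --------------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor with no tape")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data) if grad is None else np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._from_op(np.concatenate([t.data for t in tensors], axis=axis),
                           tensors, backward)


def segment_sum(values: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum ``values`` rows into ``num_segments`` buckets given by ``segment_ids``."""
    values = Tensor._lift(values)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out = np.zeros((num_segments,) + values.data.shape[1:], dtype=np.float64)
    np.add.at(out, segment_ids, values.data)

    def backward(g: np.ndarray) -> None:
        if values.requires_grad:
            values._accumulate(g[segment_ids])

    return Tensor._from_op(out, (values,), backward)


def segment_softmax(logits: Tensor, segment_ids: np.ndarray,
                    num_segments: int) -> Tensor:
    """Softmax of a flat logit vector within each segment.

    Numerically stabilized by subtracting the (constant) per-segment max.
    Output rows belonging to one segment sum to 1.
    """
    logits = Tensor._lift(logits)
    if np.any(~np.isfinite(logits.data)):
        raise ValueError("non-finite attention logits")
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    smax = np.full(num_segments, -np.inf)
    np.maximum.at(smax, segment_ids, logits.data)
    shifted = logits - Tensor(smax[segment_ids])
    ex = shifted.exp()
    denom = segment_sum(ex, segment_ids, num_segments)
    return ex / denom.gather(segment_ids)
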