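"""Minimal reverse-mode automatic differentiation over numpy arrays.

The networks in this package (gated convolutions, graph convolution /
attention layers, cross-attention) are small enough that a compact tape-based
engine over dense numpy arrays is sufficient: every operation records its
parents and a closure that propagates the upstream gradient. Gradients flow
only into tensors created with ``requires_grad=True`` (parameters) or tensors
depending on them, so fixed inputs such as embedding matrices cost nothing
extra on the backward pass.

Shapes follow numpy broadcasting; the backward of a broadcast op sums the
gradient over the broadcast axes (``_unbroadcast``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def detach(self) -> np.ndarray:
        return self.data

    def backward(self, grad=None) -> None:
        """Reverse-accumulate gradients from this (typically scalar) node."""
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order by DFS
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the tape reference; leaf grads persist
                if node is not self:
                    node._backward = None
                    node._parents = ()

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    # Python scalars are folded in directly (keeps float32 graphs float32).
    def __add__(self, other):
        if isinstance(other, (int, float)):
            c = other

            def backward_s(g):
                self._accum(g)

            return self._make(self.data + c, (self,), backward_s)
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            c = other

            def backward_s(g):
                self._accum(g * c)

            return self._make(self.data * c, (self,), backward_s)
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = _as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data**2))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        # slices / ints address disjoint memory, so plain += is safe and much
        # faster than the buffered np.add.at needed for fancy indices
        simple = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple) and all(isinstance(i, (int, slice)) for i in idx))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if simple:
                    full[idx] += g
                else:
                    np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def abs(self):
        def backward(g):
            self._accum(g * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), backward)

    def sigmoid(self):
        # exp overflow for very negative inputs saturates to 0 by design
        with np.errstate(over="ignore"):
            out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(np.where(mask, self.data, 0.0), (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        factor = np.where(mask, 1.0, slope)

        def backward(g):
            self._accum(g * factor)

        return self._make(self.data * factor, (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------------- softmax
    def softmax(self, axis=-1):
        """Numerically stable softmax as a single fused primitive."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    # ----------------------------------------------------------------- shape
    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    @property
    def T(self):
        def backward(g):
            self._accum(g.T)

        return self._make(self.data.T, (self,), backward)

    def pad_rows(self, before: int, after: int):
        """Zero-pad along axis 0 (sequence axis)."""
        width = [(before, after)] + [(0, 0)] * (self.data.ndim - 1)
        out_data = np.pad(self.data, width)
        n = self.data.shape[0]

        def backward(g):
            self._accum(g[before : before + n])

        return self._make(out_data, (self,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along `axis`."""
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = backward
    return out


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Stack 1-D tensors into a 2-D tensor (rows)."""
    return concat([t.reshape(1, -1) for t in tensors], axis=0)
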