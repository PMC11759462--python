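"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine: each :class:`Tensor` wraps an ``ndarray`` and
remembers the operation that produced it, so ``backward()`` on a scalar
accumulates gradients into every reachable leaf with ``requires_grad=True``.
Broadcasting follows NumPy semantics; gradients of broadcast operands are
sum-reduced back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` so its shape matches ``shape`` (inverse broadcast)."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward  # fn(out_grad) -> None, accumulates into parents

    # ------------------------------------------------------------------ basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative topological sort (graphs can be deep for long pipelines)
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        stack.clear()
        while visiting:
            node, processed = visiting.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visiting.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    visiting.append((p, False))
        grads: dict[int, np.ndarray] = {
            id(self): np.asarray(grad, dtype=self.data.dtype)
        }
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            node._accumulate(g)
            if node._backward is not None:
                node._backward(g, grads)

    # ---------------------------------------------------------------- helpers
    @staticmethod
    def _send(grads: dict, parent: "Tensor", g: np.ndarray) -> None:
        if not parent.requires_grad:
            return
        key = id(parent)
        if key in grads:
            grads[key] = grads[key] + g
        else:
            grads[key] = g

    # -------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g, grads):
            Tensor._send(grads, self, _unbroadcast(g, self.data.shape))
            Tensor._send(grads, other, _unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, grads):
            Tensor._send(grads, self, -g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g, grads):
            Tensor._send(grads, self, _unbroadcast(g * other.data, self.data.shape))
            Tensor._send(grads, other, _unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g, grads):
            Tensor._send(grads, self, _unbroadcast(g / other.data, self.data.shape))
            Tensor._send(
                grads, other,
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        return Tensor(self.data / other.data, _parents=(self, other), _backward=bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        def bw(g, grads):
            Tensor._send(grads, self, g * p * self.data ** (p - 1))

        return Tensor(self.data**p, _parents=(self,), _backward=bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        out = self.data @ other.data

        def bw(g, grads):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                Tensor._send(grads, self, g * b)
                Tensor._send(grads, other, g * a)
                return
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)[..., 0]
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            Tensor._send(grads, self, _unbroadcast(ga, a.shape))
            Tensor._send(grads, other, _unbroadcast(gb, b.shape))

        return Tensor(out, _parents=(self, other), _backward=bw)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        def bw(g, grads):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            Tensor._send(grads, self, np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,), _backward=bw
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out = np.exp(self.data)

        def bw(g, grads):
            Tensor._send(grads, self, g * out)

        return Tensor(out, _parents=(self,), _backward=bw)

    def log(self):
        def bw(g, grads):
            Tensor._send(grads, self, g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bw)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bw(g, grads):
            Tensor._send(grads, self, g * 0.5 / out)

        return Tensor(out, _parents=(self,), _backward=bw)

    def tanh(self):
        out = np.tanh(self.data)

        def bw(g, grads):
            Tensor._send(grads, self, g * (1.0 - out**2))

        return Tensor(out, _parents=(self,), _backward=bw)

    def leaky_relu(self, negative_slope: float = 0.01):
        mask = self.data >= 0
        out = np.where(mask, self.data, negative_slope * self.data)

        def bw(g, grads):
            Tensor._send(grads, self, g * np.where(mask, 1.0, negative_slope))

        return Tensor(out, _parents=(self,), _backward=bw)

    # ---------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g, grads):
            Tensor._send(grads, self, g.reshape(old))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g, grads):
            Tensor._send(grads, self, g.transpose(inv))

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=bw)

    def __getitem__(self, idx):
        def bw(g, grads):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            Tensor._send(grads, self, full)

        return Tensor(self.data[idx], _parents=(self,), _backward=bw)

    # ------------------------------------------------------------ compositions
    def softmax(self, axis=-1):
        """Numerically stable softmax along ``axis`` (max is detached)."""
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis=-1, keepdims=False):
        m = Tensor(self.data.max(axis=axis, keepdims=True))
        out = (self - m).exp().sum(axis=axis, keepdims=True).log() + m
        if not keepdims:
            out = out.reshape(tuple(np.delete(out.data.shape, axis)))
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g, grads):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            Tensor._send(grads, t, g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bw,
    )


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bw(g, grads):
        for i, t in enumerate(tensors):
            Tensor._send(grads, t, np.take(g, i, axis=axis))

    return Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bw,
    )
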