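"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine: each :class:`Tensor` wraps an ``ndarray`` and
remembers the tensors it was computed from together with a closure that
propagates the upstream gradient.  ``Tensor.backward()`` runs the tape in
reverse topological order.  Shapes follow numpy broadcasting; gradients of
broadcast operands are summed back to the operand's shape.

The engine is deliberately minimal: only the operations the models in this
package need are implemented, all in float64, which keeps finite-difference
gradient checks tight.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "concatenate", "stack",
           "default_dtype", "set_default_dtype", "get_default_dtype"]

_grad_enabled = True
_default_dtype = np.float64


def set_default_dtype(dtype) -> None:
    """Set the dtype new tensors are created with (float32 or float64).

    Results of operations keep the dtype numpy promotion gives them, so a
    float32 model evaluated under a float64 context simply promotes.
    """
    global _default_dtype
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("default dtype must be float32 or float64")
    _default_dtype = np.dtype(dtype).type


def get_default_dtype():
    return _default_dtype


class default_dtype:
    """Context manager scoping the default tensor dtype."""

    def __init__(self, dtype):
        self._dtype = dtype

    def __enter__(self):
        self._prev = _default_dtype
        set_default_dtype(self._dtype)
        return self

    def __exit__(self, *exc):
        set_default_dtype(self._prev)
        return False


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    """Overflow-free logistic: exp only ever sees non-positive arguments."""
    z = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + z), z / (1.0 + z))


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_accumulate")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_default_dtype)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        parents = tuple(p for p in parents if p.requires_grad)
        out = Tensor.__new__(Tensor)
        out.data = data  # keep the dtype numpy promotion produced
        out.grad = None
        out.requires_grad = bool(parents) and _grad_enabled
        out._parents = parents if out.requires_grad else ()
        out._backward = backward if out.requires_grad else None
        return out

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

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- autograd -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be provided for non-scalar outputs")
            grad = np.ones_like(self.data)
        # topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        grads: dict[int, np.ndarray] = {
            id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf: accumulate into .grad
                node.grad = g if node.grad is None else node.grad + g
            else:
                node._accumulate = grads  # type: ignore[attr-defined]
                node._backward(g)

    def _send(self, parent: "Tensor", g: np.ndarray) -> None:
        """Route gradient ``g`` to ``parent`` during backward."""
        if not parent.requires_grad:
            return
        store: dict[int, np.ndarray] = self._accumulate  # type: ignore[attr-defined]
        key = id(parent)
        if key in store:
            store[key] = store[key] + g
        else:
            store[key] = g

    # -- arithmetic -----------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        a, b = self, self._coerce(other)
        out_data = a.data + b.data

        def bw(g):
            out._send(a, _unbroadcast(g, a.data.shape))
            out._send(b, _unbroadcast(g, b.data.shape))

        out = Tensor._make(out_data, (a, b), bw)
        return out

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            out._send(a, -g)

        out = Tensor._make(-a.data, (a,), bw)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, self._coerce(other)

        def bw(g):
            out._send(a, _unbroadcast(g * b.data, a.data.shape))
            out._send(b, _unbroadcast(g * a.data, b.data.shape))

        out = Tensor._make(a.data * b.data, (a, b), bw)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, self._coerce(other)

        def bw(g):
            out._send(a, _unbroadcast(g / b.data, a.data.shape))
            out._send(b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        out = Tensor._make(a.data / b.data, (a, b), bw)
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def bw(g):
            out._send(a, g * e * a.data ** (e - 1.0))

        out = Tensor._make(a.data ** e, (a,), bw)
        return out

    def __matmul__(self, other):
        a, b = self, self._coerce(other)

        def bw(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                out._send(a, _unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                out._send(b, _unbroadcast(gb, b.data.shape))

        out = Tensor._make(np.matmul(a.data, b.data), (a, b), bw)
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            out._send(a, g * out_data)

        out = Tensor._make(out_data, (a,), bw)
        return out

    def log(self):
        a = self

        def bw(g):
            out._send(a, g / a.data)

        out = Tensor._make(np.log(a.data), (a,), bw)
        return out

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            out._send(a, g * 0.5 / out_data)

        out = Tensor._make(out_data, (a,), bw)
        return out

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            out._send(a, g * (1.0 - out_data ** 2))

        out = Tensor._make(out_data, (a,), bw)
        return out

    def sigmoid(self):
        a = self
        out_data = _stable_sigmoid(a.data)

        def bw(g):
            out._send(a, g * out_data * (1.0 - out_data))

        out = Tensor._make(out_data, (a,), bw)
        return out

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            out._send(a, g * mask)

        out = Tensor._make(a.data * mask, (a,), bw)
        return out

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def bw(g):
            out._send(a, g * sign)

        out = Tensor._make(np.abs(a.data), (a,), bw)
        return out

    # -- fused composites (single tape node each; keeps step cost low) -------
    def gelu(self):
        """Fused GELU (sigmoid approximation x * sigma(1.702 x)) with
        closed-form derivative."""
        a = self
        x = a.data
        s = _stable_sigmoid(1.702 * x)
        out_data = x * s

        def bw(g):
            out._send(a, g * (s + 1.702 * x * s * (1.0 - s)))

        out = Tensor._make(out_data, (a,), bw)
        return out

    def softmax_lastaxis(self, neg_mask: np.ndarray | None = None):
        """Fused, numerically stable softmax over the last axis.

        ``neg_mask`` (broadcastable, 1 = keep) excludes positions entirely.
        """
        a = self
        logits = a.data
        if neg_mask is not None:
            logits = logits + (1.0 - neg_mask) * -1e30
        shifted = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=-1, keepdims=True)

        def bw(g):
            dot = (g * y).sum(axis=-1, keepdims=True)
            out._send(a, y * (g - dot))

        out = Tensor._make(y, (a,), bw)
        return out

    def normalize_lastaxis(self, eps: float = 1e-6):
        """Fused zero-mean unit-variance normalization over the last axis."""
        a = self
        x = a.data
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv

        def bw(g):
            gm = g.mean(axis=-1, keepdims=True)
            gx = (g * xhat).mean(axis=-1, keepdims=True)
            out._send(a, inv * (g - gm - xhat * gx))

        out = Tensor._make(xhat, (a,), bw)
        return out

    def clip(self, lo: float, hi: float):
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def bw(g):
            out._send(a, g * mask)

        out = Tensor._make(np.clip(a.data, lo, hi), (a,), bw)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g_ = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a_norm_axes(axes, a.data.ndim)):
                    g_ = np.expand_dims(g_, ax)
            out._send(a, np.broadcast_to(g_, a.data.shape).copy())

        out = Tensor._make(out_data, (a,), bw)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else _axis_size(self.data.shape, axis)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.max(axis=axis, keepdims=keepdims)

        def bw(g):
            expanded = a.data.max(axis=axis, keepdims=True)
            mask = (a.data == expanded).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)
            g_ = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a_norm_axes(axes, a.data.ndim)):
                    g_ = np.expand_dims(g_, ax)
            out._send(a, mask * g_)

        out = Tensor._make(out_data, (a,), bw)
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def bw(g):
            out._send(a, g.reshape(orig))

        out = Tensor._make(a.data.reshape(shape), (a,), bw)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bw(g):
            out._send(a, g.transpose(inv))

        out = Tensor._make(a.data.transpose(axes), (a,), bw)
        return out

    def swapaxes(self, ax1: int, ax2: int):
        axes = list(range(self.data.ndim))
        axes[ax1], axes[ax2] = axes[ax2], axes[ax1]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            out._send(a, full)

        out = Tensor._make(a.data[idx], (a,), bw)
        return out


def a_norm_axes(axes: Iterable[int], ndim: int) -> list[int]:
    return [ax % ndim for ax in axes]


def _axis_size(shape: tuple[int, ...], axis) -> int:
    axes = axis if isinstance(axis, tuple) else (axis,)
    n = 1
    for ax in axes:
        n *= shape[ax % len(shape)]
    return n


class Parameter(Tensor):
    """A trainable tensor (leaf with requires_grad=True)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            out._send(t, p)

    out = Tensor._make(data, tensors, bw)
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            out._send(t, np.squeeze(p, axis=axis))

    out = Tensor._make(data, tensors, bw)
    return out
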