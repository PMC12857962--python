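"""Neural-network building blocks: modules, layers, and the AdamW optimizer.

Everything is seeded explicitly — layers draw their initial weights from the
``numpy.random.Generator`` passed to their constructor, so a fixed seed gives
bit-identical models.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Parameter, Tensor, concatenate

__all__ = [
    "Module", "Linear", "Embedding", "LayerNorm", "Sequential",
    "softmax", "masked_softmax", "gelu", "dropout", "AdamW", "cosine_lr",
    "clip_grad_norm",
]


class Module:
    """Minimal module container: tracks parameters and submodules by attribute."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            p.data = np.asarray(state[name], dtype=np.float64).reshape(p.data.shape)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = 1.0 / math.sqrt(d_in)
        self.W = Parameter(rng.uniform(-scale, scale, size=(d_in, d_out)))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator,
                 scale: float = 0.02):
        self.table = Parameter(rng.normal(0.0, scale, size=(n_vocab, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.table[np.asarray(idx, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.normalize_lastaxis(self._eps) * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def __call__(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    if axis in (-1, x.ndim - 1):
        return x.softmax_lastaxis()
    return x.swapaxes(axis, -1).softmax_lastaxis().swapaxes(axis, -1)


def masked_softmax(x: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over ``axis`` with positions where ``mask`` is 0 excluded
    (their weight is exactly 0 after normalization)."""
    mask = np.asarray(mask, dtype=x.data.dtype)
    if axis in (-1, x.ndim - 1):
        return x.softmax_lastaxis(neg_mask=mask)
    return x.swapaxes(axis, -1).softmax_lastaxis(
        neg_mask=np.swapaxes(mask, axis, -1)).swapaxes(axis, -1)


def gelu(x: Tensor) -> Tensor:
    """GELU, tanh approximation."""
    return x.gelu()


def dropout(x: Tensor, p: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    keep = rng.random(x.shape) >= p
    return x * Tensor(keep.astype(x.data.dtype) / np.asarray(1.0 - p, dtype=x.data.dtype))


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = math.sqrt(total)
    if norm > max_norm and norm > 0.0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


def cosine_lr(base_lr: float, step: int, total_steps: int) -> float:
    """Cosine annealing from base_lr to 0 over ``total_steps`` (no restarts)."""
    if total_steps <= 1:
        return base_lr
    t = min(step, total_steps - 1) / (total_steps - 1)
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * t))


class AdamW:
    """AdamW with decoupled weight decay (decay defaults to 0: the training
    objective carries its own explicit L2 term)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data = p.data - lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
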