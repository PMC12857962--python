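"""Drug-pair feature construction, the prediction head, and the training
objective.

A pair of drug vectors (h_i, h_j) becomes

    h_pair = [h_i ; h_j ; h_i * h_j ; |h_i - h_j|]

(concatenation, elementwise product, elementwise absolute difference), fed
to a two-hidden-layer rectifier MLP with dropout 0.3 and a sigmoid output.
The total objective is

    L_total = L_DDI + alpha * L_contrastive + beta * L_reg

with binary cross-entropy L_DDI (mean reduction by default; a literal
summed form is available) and L_reg the explicit sum of squared parameters.
Because the concatenated blocks make the raw prediction order-dependent,
inference symmetrizes: p = (p(a,b) + p(b,a)) / 2.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate
from .config import RunConfig
from .nn import Linear, Module, dropout

EPS = 1e-7


def pair_encode(h_i: Tensor, h_j: Tensor) -> Tensor:
    """[h_i ; h_j ; h_i * h_j ; |h_i - h_j|] along the last axis."""
    if h_i.shape != h_j.shape:
        raise ValueError(f"pair_encode length mismatch: {h_i.shape} vs {h_j.shape}")
    return concatenate([h_i, h_j, h_i * h_j, (h_i - h_j).abs()], axis=-1)


class PredictionHead(Module):
    """Two hidden rectifier layers with dropout, sigmoid output in (0, 1)."""

    def __init__(self, d_model: int, cfg: RunConfig, rng: np.random.Generator):
        d1, d2 = cfg.head_dims
        self.cfg = cfg
        self.fc1 = Linear(4 * d_model, d1, rng)
        self.fc2 = Linear(d1, d2, rng)
        self.out = Linear(d2, 1, rng)

    def __call__(self, h_pair: Tensor, rng=None,
                 training: bool = False) -> Tensor:
        p = self.cfg.dropout
        h = dropout(self.fc1(h_pair).relu(), p, rng, training)
        h = dropout(self.fc2(h).relu(), p, rng, training)
        return self.out(h).sigmoid()


def bce_loss(p: Tensor, y: np.ndarray, reduction: str = "mean") -> Tensor:
    """Binary cross-entropy with probabilities clamped to [1e-7, 1 - 1e-7]."""
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    p = p.reshape(-1).clip(EPS, 1.0 - EPS)
    terms = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log())
    if reduction == "mean":
        return terms.mean()
    if reduction == "sum":
        return terms.sum()
    raise ValueError(f"unknown reduction {reduction!r}")


def l2_penalty(params: list) -> Tensor:
    """Explicit L2 term: sum of squared entries over all parameters."""
    total = None
    for p in params:
        sq = (p * p).sum()
        total = sq if total is None else total + sq
    return total if total is not None else Tensor(0.0)


def total_loss(predictions: Tensor, labels: np.ndarray,
               contrastive_term: Tensor | None, params: list,
               cfg: RunConfig) -> tuple[Tensor, dict[str, float]]:
    """L_DDI + alpha * L_contrastive + beta * L_reg, with a component log."""
    l_ddi = bce_loss(predictions, labels, cfg.bce_reduction)
    parts = {"ddi": l_ddi.item()}
    loss = l_ddi
    if contrastive_term is not None and cfg.alpha > 0:
        loss = loss + contrastive_term * cfg.alpha
        parts["contrastive"] = contrastive_term.item()
    if cfg.beta > 0:
        reg = l2_penalty(params)
        loss = loss + reg * cfg.beta
        parts["reg"] = reg.item()
    parts["total"] = loss.item()
    return loss, parts
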