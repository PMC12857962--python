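"""Projection head, InfoNCE-style contrastive objective, hard-negative mining.

For a batch of drugs with projected, L2-normalized embeddings z_i and
augmented-view embeddings z_i+, the loss is

    L = -1/B * sum_i log [ exp(sim(z_i, z_i+)/tau) / D_i ]

with cosine similarity sim and temperature tau.  Two denominator modes:
``with_positive`` includes the positive term alongside all in-batch
negatives (bounded below by 0, and consistent with the hard-mining
objective); ``literal`` keeps only the negatives.  Hard mining restricts the
negatives to the k most similar other drugs in the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .config import RunConfig
from .nn import Linear, Module

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingBatch:
    """Projected originals Z and augmented views Z_plus, rows L2-normalized
    so that dot products are cosine similarities."""
    Z: Tensor        # (B, d)
    Z_plus: Tensor   # (B, d)
    drug_ids: list[str] | None = None


class ProjectionHead(Module):
    """2-layer map d_model -> d_model -> projection_dim, used only for the
    contrastive loss; downstream consumers keep the pre-projection vector."""

    def __init__(self, d_model: int, projection_dim: int,
                 rng: np.random.Generator):
        self.fc1 = Linear(d_model, d_model, rng)
        self.fc2 = Linear(d_model, projection_dim, rng)

    def __call__(self, h: Tensor) -> Tensor:
        return self.fc2(self.fc1(h).relu())


def l2_normalize(x: Tensor, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=-1, keepdims=True) + eps).sqrt()
    return x / norm


def _check_batch(batch: EmbeddingBatch) -> int:
    B = batch.Z.shape[0]
    if B < 2:
        raise ValueError("contrastive loss needs a batch of >= 2 drugs")
    if batch.Z_plus.shape != batch.Z.shape:
        raise ValueError("Z and Z_plus shape mismatch")
    return B


def contrastive_loss(batch: EmbeddingBatch, config: RunConfig) -> Tensor:
    """Mean over anchors of -log(positive / denominator); see module doc."""
    B = _check_batch(batch)
    tau = config.temperature
    pos = (batch.Z * batch.Z_plus).sum(axis=-1) / tau       # (B,)
    sim = (batch.Z @ batch.Z.swapaxes(-1, -2)) / tau        # (B, B)
    off_diag = 1.0 - np.eye(B)
    # subtract a detached per-row max for numerical stability
    m = np.maximum(pos.data, (sim.data * off_diag - 1e30 * np.eye(B)).max(axis=-1))
    pos_e = (pos - Tensor(m)).exp()
    neg_e = ((sim - Tensor(m[:, None])).exp() * Tensor(off_diag)).sum(axis=-1)
    if config.denominator_mode == "with_positive":
        denom = pos_e + neg_e
    elif config.denominator_mode == "literal":
        denom = neg_e
    else:
        raise ValueError(f"unknown denominator_mode {config.denominator_mode!r}")
    losses = -((pos_e / denom).log())
    return losses.mean()


def mine_hard_negatives(batch: EmbeddingBatch, k: int) -> np.ndarray:
    """Indices of the k most similar other drugs per anchor, shape (B, k).

    Deterministic: ties break by ascending index.  k > B-1 clamps with a
    warning.
    """
    B = _check_batch(batch)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > B - 1:
        logger.warning("hard_negative_k=%d > B-1=%d; clamping", k, B - 1)
        k = B - 1
    sim = batch.Z.data @ batch.Z.data.T
    np.fill_diagonal(sim, -np.inf)
    # stable top-k with ascending-index tie-break: sort by (-sim, index)
    order = np.lexsort((np.tile(np.arange(B), (B, 1)), -sim), axis=-1)
    return order[:, :k]


def hard_contrastive_loss(batch: EmbeddingBatch, config: RunConfig) -> Tensor:
    """Contrastive loss whose denominator keeps the positive term plus the k
    hardest in-batch negatives only."""
    B = _check_batch(batch)
    tau = config.temperature
    hard_idx = mine_hard_negatives(batch, config.hard_negative_k)
    pos = (batch.Z * batch.Z_plus).sum(axis=-1) / tau
    sim = (batch.Z @ batch.Z.swapaxes(-1, -2)) / tau
    rows = np.arange(B)[:, None]
    hard_sims = sim[rows, hard_idx]                         # (B, k)
    m = np.maximum(pos.data, hard_sims.data.max(axis=-1))
    pos_e = (pos - Tensor(m)).exp()
    neg_e = (hard_sims - Tensor(m[:, None])).exp().sum(axis=-1)
    losses = -((pos_e / (pos_e + neg_e)).log())
    return losses.mean()


def batch_contrastive_loss(batch: EmbeddingBatch, config: RunConfig) -> Tensor:
    """Dispatch on config.use_hard_mining."""
    if config.use_hard_mining:
        return hard_contrastive_loss(batch, config)
    return contrastive_loss(batch, config)
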