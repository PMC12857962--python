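"""Position-aware graph transformer with hierarchical readout.

The encoder stack runs pre-norm transformer blocks whose attention logits
carry an additive spatial bias keyed on bucketed chemical distance:

    Attention(Q, K, V, S) = softmax((Q K^T + S) / sqrt(d_k)) V

followed by a three-level hierarchy: per-atom states H1, soft cluster states
H2 via differentiable pooling (row-stochastic assignment S2, coarsened
adjacency A2 = S2^T A S2), and a molecule vector h_mol via global attention
pooling over clusters.

All operations are batched over padded molecules; ``atom_mask`` marks real
atoms.  Padded keys are excluded from every softmax, padded assignment rows
are zeroed before aggregation, so results are identical to per-molecule
execution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate
from .config import RunConfig
from .nn import (LayerNorm, Linear, Module, dropout, gelu, masked_softmax,
                 softmax)

logger = logging.getLogger(__name__)


def attention_core(Q: Tensor, K: Tensor, V: Tensor, bias: Tensor | None,
                   d_k: int, key_mask: np.ndarray | None = None,
                   scale_bias_inside: bool = True) -> tuple[Tensor, Tensor]:
    """Scaled dot-product attention with additive spatial bias.

    Shapes: Q, K (..., n, d_k); V (..., n, d_v); bias broadcastable to
    (..., n, n).  Returns (output, attention weights); weight rows sum to 1.
    """
    for t in (Q, K, V):
        # a non-finite entry makes the sum non-finite; single cheap reduce
        if not np.isfinite(t.data.sum()):
            raise ValueError("non-finite attention input")
    logits = Q @ K.swapaxes(-1, -2)
    scale = 1.0 / math.sqrt(d_k)
    if bias is not None and scale_bias_inside:
        logits = (logits + bias) * scale
    else:
        logits = logits * scale
        if bias is not None:
            logits = logits + bias
    if key_mask is not None:
        weights = masked_softmax(logits, key_mask, axis=-1)
    else:
        weights = softmax(logits, axis=-1)
    return weights @ V, weights


def position_aware_attention(X: Tensor, bias_h: Tensor | None, Wq: Tensor,
                             Wk: Tensor, Wv: Tensor,
                             scale_bias_inside: bool = True) -> Tensor:
    """Single-head position-aware attention on atom states X (n, d_model)."""
    d_k = Wq.shape[-1]
    out, _ = attention_core(X @ Wq, X @ Wk, X @ Wv, bias_h, d_k,
                            scale_bias_inside=scale_bias_inside)
    return out


class MultiHeadAttention(Module):
    """H parallel position-aware heads, concatenated and projected by W^O."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must divide by n_heads")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.Wq = Linear(d_model, d_model, rng, bias=False)
        self.Wk = Linear(d_model, d_model, rng, bias=False)
        self.Wv = Linear(d_model, d_model, rng, bias=False)
        self.Wo = Linear(d_model, d_model, rng, bias=False)

    def head_params(self, h: int) -> tuple[Tensor, Tensor, Tensor]:
        """Per-head projection slices W_h^Q, W_h^K, W_h^V (d_model x d_k)."""
        sl = slice(h * self.d_k, (h + 1) * self.d_k)
        return (self.Wq.W[:, sl], self.Wk.W[:, sl], self.Wv.W[:, sl])

    def _split(self, t: Tensor, B: int, N: int) -> Tensor:
        # (B, N, d_model) -> (B, H, N, d_k)
        return t.reshape(B, N, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def __call__(self, X: Tensor, bias: Tensor | None,
                 atom_mask: np.ndarray | None = None,
                 scale_bias_inside: bool = True) -> Tensor:
        B, N, _ = X.shape
        Q = self._split(self.Wq(X), B, N)
        K = self._split(self.Wk(X), B, N)
        V = self._split(self.Wv(X), B, N)
        key_mask = None
        if atom_mask is not None:
            key_mask = atom_mask[:, None, None, :]  # broadcast over heads, queries
        out, _ = attention_core(Q, K, V, bias, self.d_k, key_mask,
                                scale_bias_inside)
        out = out.transpose(0, 2, 1, 3).reshape(B, N, self.d_model)
        return self.Wo(out)


class FeedForward(Module):
    def __init__(self, d_model: int, mult: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, mult * d_model, rng)
        self.fc2 = Linear(mult * d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class GCNLayer(Module):
    """Normalized-adjacency message passing (baseline mode substitute for
    attention): X' = D^{-1/2} (A + I) D^{-1/2} X W."""

    def __init__(self, d_model: int, rng: np.random.Generator):
        self.W = Linear(d_model, d_model, rng)

    def __call__(self, X: Tensor, A_hat: np.ndarray) -> Tensor:
        return Tensor(A_hat) @ self.W(X)


def normalized_adjacency(A: np.ndarray,
                         atom_mask: np.ndarray | None = None) -> np.ndarray:
    """Symmetric normalization of A + I, restricted to real atoms."""
    A = np.asarray(A, dtype=np.float64)
    eye = np.eye(A.shape[-1])
    if atom_mask is not None:
        m = atom_mask[..., :, None] * atom_mask[..., None, :]
        A_hat = A * m + eye * atom_mask[..., :, None]
    else:
        A_hat = A + eye
    deg = A_hat.sum(axis=-1)
    inv_sqrt = np.where(deg > 0, deg, 1.0) ** -0.5
    return A_hat * inv_sqrt[..., :, None] * inv_sqrt[..., None, :]


class EncoderBlock(Module):
    """Pre-norm block: x + Drop(MHA(LN(x))); x + Drop(FFN(LN(x)))."""

    def __init__(self, cfg: RunConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.ln1 = LayerNorm(cfg.d_model)
        self.ln2 = LayerNorm(cfg.d_model)
        if cfg.gcn_baseline_mode:
            self.gcn = GCNLayer(cfg.d_model, rng)
        else:
            self.attn = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.ffn = FeedForward(cfg.d_model, cfg.ffn_mult, rng)

    def __call__(self, X: Tensor, bias: Tensor | None, atom_mask: np.ndarray,
                 A_hat: np.ndarray | None, rng, training: bool) -> Tensor:
        p = self.cfg.dropout
        if self.cfg.gcn_baseline_mode:
            h = self.gcn(self.ln1(X), A_hat)
        else:
            h = self.attn(self.ln1(X), bias, atom_mask,
                          self.cfg.scale_bias_inside)
        X = X + dropout(h, p, rng, training)
        X = X + dropout(self.ffn(self.ln2(X)), p, rng, training)
        return X


class GraphEncoder(Module):
    """Input projection + n_layers position-aware transformer blocks -> H1."""

    def __init__(self, d_atom: int, cfg: RunConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.input_proj = Linear(d_atom, cfg.d_model, rng)
        self.blocks = [EncoderBlock(cfg, rng) for _ in range(cfg.n_layers)]

    def __call__(self, Xv: np.ndarray | Tensor, bias: Tensor | None,
                 atom_mask: np.ndarray, A: np.ndarray | None = None,
                 rng=None, training: bool = False) -> Tensor:
        X = Xv if isinstance(Xv, Tensor) else Tensor(Xv)
        H = self.input_proj(X)
        A_hat = None
        if self.cfg.gcn_baseline_mode:
            if A is None:
                raise ValueError("gcn_baseline_mode requires adjacency")
            A_hat = normalized_adjacency(A, atom_mask)
        for block in self.blocks:
            H = block(H, bias, atom_mask, A_hat, rng, training)
        return H * Tensor(atom_mask[..., None])  # zero padded rows


@dataclass
class PoolResult:
    S2: Tensor        # (B, N, K) row-stochastic on real atoms
    H2: Tensor        # (B, K, d_model)
    A2: Tensor        # (B, K, K)
    cluster_mask: np.ndarray  # (B, K) 1 = active cluster for that molecule
    link_loss: Tensor
    entropy_loss: Tensor


class DiffPool(Module):
    """One differentiable pooling level: atoms -> K soft clusters.

    Assignment scores come from node states concatenated with one step of
    adjacency smoothing, so topology informs cluster membership.  Optional
    auxiliary link-prediction and assignment-entropy losses are returned
    (weight 0 by default at the model level).
    """

    def __init__(self, d_model: int, max_clusters: int,
                 rng: np.random.Generator):
        self.max_clusters = max_clusters
        self.embed = Linear(d_model, d_model, rng)
        self.assign = Linear(2 * d_model, max_clusters, rng)

    def __call__(self, H1: Tensor, A: np.ndarray, atom_mask: np.ndarray,
                 k: int | np.ndarray | None = None) -> PoolResult:
        """``k`` may be a scalar or per-molecule array; inactive cluster
        columns are masked out of the assignment softmax, so each molecule's
        pooling is independent of what else shares the padded batch."""
        B, N, _ = H1.shape
        if k is None:
            k = self.max_clusters
        ks = np.minimum(np.broadcast_to(np.asarray(k, dtype=np.intp), (B,)),
                        self.max_clusters)
        k_max = int(ks.max())
        if np.any(ks >= np.asarray(atom_mask).sum(-1)):
            logger.info("DiffPool over-clustering for some molecules")
        cluster_mask = (np.arange(k_max)[None, :] < ks[:, None]).astype(float)
        A_hat = normalized_adjacency(A, atom_mask)
        smoothed = Tensor(A_hat) @ H1
        scores = self.assign(concatenate([H1, smoothed], axis=-1))
        scores = scores[:, :, :k_max]
        S2 = masked_softmax(scores, cluster_mask[:, None, :], axis=-1) \
            * Tensor(atom_mask[..., None])
        Z = self.embed(H1)
        S2t = S2.swapaxes(-1, -2)
        H2 = S2t @ Z
        A2 = S2t @ (Tensor(np.asarray(A, dtype=np.float64)) @ S2)
        # auxiliary losses (returned; weighting decided by caller)
        pair_mask = atom_mask[..., :, None] * atom_mask[..., None, :]
        diff = (S2 @ S2t - Tensor(np.asarray(A, dtype=np.float64))) * Tensor(pair_mask)
        denom = max(float(pair_mask.sum()), 1.0)
        link_loss = (diff * diff).sum() * (1.0 / denom)
        ent = -(S2 * (S2 + 1e-12).log()).sum(axis=-1)
        entropy_loss = ent.sum() * (1.0 / max(float(atom_mask.sum()), 1.0))
        return PoolResult(S2=S2, H2=H2, A2=A2, cluster_mask=cluster_mask,
                          link_loss=link_loss, entropy_loss=entropy_loss)


class GlobalAttentionPool(Module):
    """Gated readout over cluster states: h_mol = sum_k g_k * value(H2_k),
    with gate scores g = softmax over clusters."""

    def __init__(self, d_model: int, rng: np.random.Generator):
        self.gate_hidden = Linear(d_model, d_model, rng)
        self.gate_out = Linear(d_model, 1, rng)
        self.value = Linear(d_model, d_model, rng)

    def __call__(self, H2: Tensor,
                 cluster_mask: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
        logits = self.gate_out(self.gate_hidden(H2).tanh())  # (B, K, 1)
        logits = logits.swapaxes(-1, -2)                     # (B, 1, K)
        if cluster_mask is not None:
            gates = masked_softmax(logits, cluster_mask[:, None, :], axis=-1)
        else:
            gates = softmax(logits, axis=-1)
        h_mol = (gates @ self.value(H2)).reshape(H2.shape[0], H2.shape[2])
        return h_mol, gates.reshape(H2.shape[0], H2.shape[1])


def auto_clusters(n: int, cap: int = 16) -> int:
    """Default cluster count: max(2, ceil(n / 4)), capped."""
    return min(cap, max(2, math.ceil(n / 4)))
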