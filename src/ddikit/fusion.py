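"""Cross-modal fusion: SMILES sequence encoding, graph<->sequence
cross-attention, and the adaptive gated combination of the two modalities.

The default sequence encoder is a small trainable transformer over a
character-level SMILES vocabulary (two-character element tokens Cl and Br
are single tokens).  Any external encoder exposing ``(token_states, pooled)``
can be plugged in behind the same interface.

Fusion:  h_final = lambda * h_graph + (1 - lambda) * h_smiles, with the
scalar gate lambda = sigmoid(MLP([h_graph ; h_smiles])) learned per drug.
The sequence vector is linearly projected to d_model first, so the convex
combination type-checks when d_bert != d_model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate
from .config import RunConfig
from .nn import (LayerNorm, Linear, Module, dropout, gelu, masked_softmax,
                 softmax)
from .transformer import attention_core

logger = logging.getLogger(__name__)

# Character-level SMILES vocabulary; greedy longest-match tokenizer.
MULTI_CHAR_TOKENS = ("Cl", "Br")
SINGLE_CHAR_TOKENS = tuple("BCNOPSFI") + tuple("bcnops") + tuple("0123456789") \
    + tuple("()[]=#:+-*@/\\%Hhe")
PAD, UNK = "<pad>", "<unk>"
VOCAB = (PAD, UNK) + MULTI_CHAR_TOKENS + SINGLE_CHAR_TOKENS
TOKEN_TO_ID = {t: i for i, t in enumerate(VOCAB)}


def tokenize(smiles: str) -> list[str]:
    """Greedy longest-match tokenization; unknown characters map to <unk>."""
    tokens: list[str] = []
    i = 0
    while i < len(smiles):
        two = smiles[i:i + 2]
        if two in MULTI_CHAR_TOKENS:
            tokens.append(two)
            i += 2
            continue
        ch = smiles[i]
        if ch in TOKEN_TO_ID:
            tokens.append(ch)
        else:
            logger.info("unknown SMILES character %r -> <unk>", ch)
            tokens.append(UNK)
        i += 1
    return tokens


def encode_tokens(smiles: str, max_len: int) -> np.ndarray:
    toks = tokenize(smiles)[:max_len]
    return np.asarray([TOKEN_TO_ID.get(t, TOKEN_TO_ID[UNK]) for t in toks],
                      dtype=np.intp)


@dataclass
class SmilesEncoding:
    token_ids: np.ndarray    # (L,)
    token_states: Tensor     # (L, d_bert)
    pooled: Tensor           # (d_bert,)


class SequenceEncoder(Module):
    """Small trainable transformer over SMILES tokens.

    Token + learned positional embeddings, ``seq_layers`` pre-norm blocks,
    masked mean pooling.  Works on padded batches: ``__call__`` takes
    (B, L) ids with 0 = padding.
    """

    def __init__(self, cfg: RunConfig, rng: np.random.Generator):
        from .nn import Embedding
        self.cfg = cfg
        d = cfg.d_bert
        self.tok = Embedding(len(VOCAB), d, rng)
        self.pos = Embedding(cfg.seq_max_len, d, rng)
        self.blocks = [_SeqBlock(d, cfg.seq_heads, rng)
                       for _ in range(cfg.seq_layers)]
        self.ln_out = LayerNorm(d)

    def __call__(self, ids: np.ndarray, rng=None,
                 training: bool = False) -> tuple[Tensor, np.ndarray]:
        """ids (B, L) -> (token states (B, L, d_bert), token mask (B, L))."""
        ids = np.asarray(ids, dtype=np.intp)
        B, L = ids.shape
        mask = (ids != TOKEN_TO_ID[PAD]).astype(np.float64)
        X = self.tok(ids) + self.pos(np.tile(np.arange(L), (B, 1)))
        for block in self.blocks:
            X = block(X, mask, self.cfg.dropout, rng, training)
        X = self.ln_out(X)
        return X * Tensor(mask[..., None]), mask

    def pool(self, states: Tensor, mask: np.ndarray) -> Tensor:
        """Masked mean over tokens -> (B, d_bert)."""
        denom = np.maximum(mask.sum(axis=-1, keepdims=True), 1.0)
        return states.sum(axis=-2) / Tensor(denom)

    def encode_one(self, smiles: str) -> SmilesEncoding:
        ids = encode_tokens(smiles, self.cfg.seq_max_len)
        states, mask = self(ids[None, :])
        pooled = self.pool(states, mask)
        return SmilesEncoding(token_ids=ids,
                              token_states=states.reshape(len(ids), -1),
                              pooled=pooled.reshape(-1))


class _SeqBlock(Module):
    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        self.heads = heads
        self.d_k = d // heads
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.Wq = Linear(d, d, rng, bias=False)
        self.Wk = Linear(d, d, rng, bias=False)
        self.Wv = Linear(d, d, rng, bias=False)
        self.Wo = Linear(d, d, rng, bias=False)
        self.fc1 = Linear(d, 2 * d, rng)
        self.fc2 = Linear(2 * d, d, rng)

    def __call__(self, X: Tensor, mask: np.ndarray, p: float, rng,
                 training: bool) -> Tensor:
        B, L, d = X.shape
        h = self.ln1(X)

        def split(t):
            return t.reshape(B, L, self.heads, self.d_k).transpose(0, 2, 1, 3)

        out, _ = attention_core(split(self.Wq(h)), split(self.Wk(h)),
                                split(self.Wv(h)), None, self.d_k,
                                mask[:, None, None, :])
        out = out.transpose(0, 2, 1, 3).reshape(B, L, d)
        X = X + dropout(self.Wo(out), p, rng, training)
        X = X + dropout(self.fc2(gelu(self.fc1(self.ln2(X)))), p, rng, training)
        return X


class CrossAttention(Module):
    """Atom states attend over SMILES token states; output added residually.

    Scores use a learned bilinear projection to a shared dimension (the raw
    dot product of the two modalities is recovered when dimensions match and
    the projections are identity).
    """

    def __init__(self, d_model: int, d_bert: int, rng: np.random.Generator):
        self.Wq = Linear(d_model, d_model, rng, bias=False)
        self.Wk = Linear(d_bert, d_model, rng, bias=False)
        self.Wv = Linear(d_bert, d_model, rng, bias=False)

    def __call__(self, H1: Tensor, token_states: Tensor,
                 token_mask: np.ndarray,
                 atom_mask: np.ndarray | None = None
                 ) -> tuple[Tensor, Tensor]:
        """H1 (B, n, d_model), tokens (B, L, d_bert) -> (fused H1, alpha)."""
        Q = self.Wq(H1)
        K = self.Wk(token_states)
        V = self.Wv(token_states)
        logits = Q @ K.swapaxes(-1, -2)                  # (B, n, L)
        alpha = masked_softmax(logits, token_mask[:, None, :], axis=-1)
        attended = alpha @ V
        out = H1 + attended
        if atom_mask is not None:
            out = out * Tensor(atom_mask[..., None])
        return out, alpha


class AdaptiveFusion(Module):
    """Scalar gate per drug: lambda = sigmoid(MLP([h_graph ; h_smiles]))."""

    def __init__(self, d_model: int, d_bert: int, rng: np.random.Generator,
                 hidden: int | None = None):
        hidden = hidden or d_model
        self.project_seq = Linear(d_bert, d_model, rng)
        self.gate_fc1 = Linear(2 * d_model, hidden, rng)
        self.gate_fc2 = Linear(hidden, 1, rng)

    def __call__(self, h_graph: Tensor, h_smiles_raw: Tensor,
                 adaptive: bool = True) -> tuple[Tensor, Tensor]:
        """Returns (lambda (B, 1), h_final (B, d_model)).

        ``adaptive=False`` fixes lambda at 0.5 (ablation switch).
        """
        h_seq = self.project_seq(h_smiles_raw)
        if adaptive:
            lam = self.gate_fc2(self.gate_fc1(
                concatenate([h_graph, h_seq], axis=-1)).relu()).sigmoid()
        else:
            lam = Tensor(np.full((h_graph.shape[0], 1), 0.5))
        h_final = h_graph * lam + h_seq * (1.0 - lam)
        return lam, h_final
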