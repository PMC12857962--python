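"""The end-to-end DDI model: graph encoder + hierarchy + fusion + pair head.

``DDIModel.encode`` maps a list of featurized molecular graphs to fused
per-drug vectors h_final in one padded, batched pass; ``predict_pairs`` and
``symmetrized_predict`` turn two drug vectors into an interaction
probability.  All ablation switches of the run configuration are honored
here (spatial bias off, hierarchy off, fusion off, fixed gate, GCN
message-passing baseline, standard transformer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import numpy as _np

from .autodiff import Parameter, Tensor, default_dtype, no_grad
from .config import RunConfig
from .contrastive import ProjectionHead, l2_normalize
from .fusion import (AdaptiveFusion, CrossAttention, SequenceEncoder,
                     encode_tokens, TOKEN_TO_ID, PAD)
from .mol_io import DEFAULT_SCHEMA, MolecularGraph
from .nn import Module
from .prediction import PredictionHead, pair_encode
from .spatial import SpatialBias, chemical_distance
from .transformer import (DiffPool, GlobalAttentionPool, GraphEncoder,
                          auto_clusters)

MAX_CLUSTERS = 16


def spatial_buckets(graph: MolecularGraph, cfg: RunConfig) -> np.ndarray:
    """Bucketed chemical-distance matrix, cached on the graph object.

    Augmented views carry their own (recomputed) cache because topology may
    have changed; token masking and bond re-typing preserve unit-weight
    distances so reuse is safe there.
    """
    cached = getattr(graph, "_spatial_cache", None)
    key = (cfg.weight_scheme, cfg.d_max)
    if cached is not None and cached[0] == key:
        return cached[1]
    sm = chemical_distance(graph, cfg.weight_scheme, cfg.d_max)
    graph._spatial_cache = (key, sm.clipped_bucket)
    return sm.clipped_bucket


@dataclass
class MoleculeBatch:
    """Padded arrays for a batch of molecules."""
    features: np.ndarray    # (B, N, d_atom)
    atom_mask: np.ndarray   # (B, N) 1 = real atom
    mask_flags: np.ndarray  # (B, N) 1 = masked by augmentation
    buckets: np.ndarray     # (B, N, N) distance buckets
    adjacency: np.ndarray   # (B, N, N)
    token_ids: np.ndarray   # (B, L)
    n_atoms: list[int] = field(default_factory=list)


def build_batch(graphs: list[MolecularGraph], cfg: RunConfig) -> MoleculeBatch:
    B = len(graphs)
    ns = [g.n_atoms for g in graphs]
    N = max(ns)
    d_atom = DEFAULT_SCHEMA.d_atom
    feats = np.zeros((B, N, d_atom))
    amask = np.zeros((B, N))
    mflags = np.zeros((B, N))
    buckets = np.full((B, N, N), cfg.d_max + 1, dtype=np.intp)
    adj = np.zeros((B, N, N))
    tok_lists = []
    for g in graphs:
        toks = getattr(g, "_token_cache", None)
        if toks is None or len(toks) > cfg.seq_max_len:
            toks = encode_tokens(g.smiles, cfg.seq_max_len)
            g._token_cache = toks
        tok_lists.append(toks)
    L = max(max(len(t) for t in tok_lists), 1)
    tokens = np.full((B, L), TOKEN_TO_ID[PAD], dtype=np.intp)
    for b, g in enumerate(graphs):
        n = ns[b]
        if g.atom_features is None:
            raise ValueError("graphs must be featurized before batching")
        feats[b, :n] = g.atom_features
        amask[b, :n] = 1.0
        mflags[b, :n] = g.mask_flags.astype(np.float64)
        buckets[b, :n, :n] = spatial_buckets(g, cfg)
        adj[b, :n, :n] = g.adjacency()
        tokens[b, :len(tok_lists[b])] = tok_lists[b]
    return MoleculeBatch(features=feats, atom_mask=amask, mask_flags=mflags,
                         buckets=buckets, adjacency=adj, token_ids=tokens,
                         n_atoms=ns)


@dataclass
class EncodeResult:
    h_final: Tensor          # (B, d_model) fused drug vectors
    h_mol: Tensor            # (B, d_model) graph-pathway vectors
    H1: Tensor               # (B, N, d_model) atom states
    pool_aux: Tensor | None  # weighted DiffPool auxiliary loss (or None)
    gate: Tensor | None      # fusion lambda (B, 1) when fusion is on


class DDIModel(Module):
    """Complete drug-drug interaction model over molecular graphs + SMILES."""

    def __init__(self, cfg: RunConfig, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self._dtype = _np.float32 if cfg.precision == "float32" else _np.float64
        d_atom = DEFAULT_SCHEMA.d_atom
        use_bias = (cfg.spatial_bias_on and not cfg.standard_transformer_mode
                    and not cfg.gcn_baseline_mode)
        with default_dtype(self._dtype):
            self.mask_token = Parameter(rng.normal(0.0, 0.02, size=(d_atom,)))
            self.encoder = GraphEncoder(d_atom, cfg, rng)
            # disabled components are not instantiated, so ablation variants
            # carry honestly different parameter counts
            self.spatial_bias = (SpatialBias(cfg.n_heads, cfg.d_max, rng)
                                 if use_bias else None)
            self.diffpool = (DiffPool(cfg.d_model, MAX_CLUSTERS, rng)
                             if cfg.use_hier_pool else None)
            self.readout = (GlobalAttentionPool(cfg.d_model, rng)
                            if cfg.use_hier_pool else None)
            self.seq_encoder = SequenceEncoder(cfg, rng) if cfg.fusion_on else None
            self.cross_attn = (CrossAttention(cfg.d_model, cfg.d_bert, rng)
                               if cfg.fusion_on else None)
            self.fuse = (AdaptiveFusion(cfg.d_model, cfg.d_bert, rng)
                         if cfg.fusion_on else None)
            self.projection = ProjectionHead(cfg.d_model, cfg.projection_dim, rng)
            self.head = PredictionHead(cfg.d_model, cfg, rng)

    # -- encoding ------------------------------------------------------------
    def encode(self, graphs: list[MolecularGraph], rng=None,
               training: bool = False) -> EncodeResult:
        cfg = self.cfg
        batch = build_batch(graphs, cfg)
        X = Tensor(batch.features)
        if batch.mask_flags.any():
            flags = Tensor(batch.mask_flags[..., None])
            X = X * (1.0 - flags) + self.mask_token * flags
        bias = (self.spatial_bias(batch.buckets)
                if self.spatial_bias is not None else None)
        H1 = self.encoder(X, bias, batch.atom_mask, batch.adjacency, rng,
                          training)
        gate = None
        token_states = token_mask = None
        if cfg.fusion_on:
            token_states, token_mask = self.seq_encoder(batch.token_ids, rng,
                                                        training)
            H1, _ = self.cross_attn(H1, token_states, token_mask,
                                    batch.atom_mask)
        pool_aux = None
        if cfg.use_hier_pool:
            if cfg.pool_clusters:
                k = cfg.pool_clusters
            else:
                k = np.asarray([auto_clusters(n) for n in batch.n_atoms])
            pooled = self.diffpool(H1, batch.adjacency, batch.atom_mask, k)
            h_mol, _ = self.readout(pooled.H2, pooled.cluster_mask)
            if cfg.pool_aux_weight > 0:
                pool_aux = (pooled.link_loss + pooled.entropy_loss) \
                    * cfg.pool_aux_weight
        else:
            denom = np.maximum(batch.atom_mask.sum(-1, keepdims=True), 1.0)
            h_mol = H1.sum(axis=-2) / Tensor(denom)
        if cfg.fusion_on:
            h_seq = self.seq_encoder.pool(token_states, token_mask)
            gate, h_final = self.fuse(h_mol, h_seq, cfg.adaptive_fusion_on)
        else:
            h_final = h_mol
        return EncodeResult(h_final=h_final, h_mol=h_mol, H1=H1,
                            pool_aux=pool_aux, gate=gate)

    def project(self, h: Tensor) -> Tensor:
        """L2-normalized contrastive projection of drug vectors."""
        return l2_normalize(self.projection(h))

    # -- prediction ----------------------------------------------------------
    def predict_pairs(self, h_a: Tensor, h_b: Tensor, rng=None,
                      training: bool = False) -> Tensor:
        """Raw (order-dependent) interaction probabilities, shape (B,)."""
        p = self.head(pair_encode(h_a, h_b), rng, training)
        return p.reshape(-1)

    def symmetrized_predict(self, h_a: Tensor, h_b: Tensor) -> Tensor:
        """Order-invariant probability: mean of both argument orders."""
        return (self.predict_pairs(h_a, h_b)
                + self.predict_pairs(h_b, h_a)) * 0.5

    def infer_pairs(self, graphs_a: list[MolecularGraph],
                    graphs_b: list[MolecularGraph]) -> np.ndarray:
        """Inference-mode probabilities for aligned drug lists."""
        with no_grad(), default_dtype(self._dtype):
            h = self.encode(graphs_a + graphs_b).h_final
            B = len(graphs_a)
            h_a, h_b = h[:B], h[B:]
            if self.cfg.symmetrize_inference:
                p = self.symmetrized_predict(h_a, h_b)
            else:
                p = self.predict_pairs(h_a, h_b)
        return p.data.copy()
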