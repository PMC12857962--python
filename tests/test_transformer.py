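"""Position-aware attention, the encoder stack, and hierarchical pooling."""

import numpy as np
import pytest

from conftest import numerical_gradient, relative_error
from ddikit.autodiff import Parameter, Tensor
from ddikit.config import RunConfig
from ddikit.transformer import (DiffPool, GlobalAttentionPool, GraphEncoder,
                                MultiHeadAttention, attention_core,
                                auto_clusters, normalized_adjacency,
                                position_aware_attention)

RNG = np.random.default_rng(11)


def double_loop_attention(X, bias, Wq, Wk, Wv, d_k):
    """Explicit per-pair exp/normalize oracle, independent of the
    vectorized implementation."""
    Q, K, V = X @ Wq, X @ Wk, X @ Wv
    n = X.shape[0]
    out = np.zeros_like(V)
    for i in range(n):
        logits = np.array([(Q[i] @ K[j] + (bias[i, j] if bias is not None
                                           else 0.0)) / np.sqrt(d_k)
                           for j in range(n)])
        w = np.exp(logits - logits.max())
        w /= w.sum()
        for j in range(n):
            out[i] += w[j] * V[j]
    return out


class TestAttentionKernel:
    def test_matches_double_loop_oracle(self):
        for _ in range(10):
            n, d = 5, 8
            X = RNG.normal(size=(n, d))
            bias = RNG.normal(size=(n, n))
            Wq, Wk, Wv = (RNG.normal(size=(d, d)) for _ in range(3))
            got = position_aware_attention(
                Tensor(X), Tensor(bias), Tensor(Wq), Tensor(Wk), Tensor(Wv))
            want = double_loop_attention(X, bias, Wq, Wk, Wv, d)
            assert np.abs(got.data - want).max() < 1e-5

    def test_zero_bias_equals_standard_attention(self):
        n, d = 6, 4
        X = RNG.normal(size=(n, d))
        Wq, Wk, Wv = (RNG.normal(size=(d, d)) for _ in range(3))
        with_zero = position_aware_attention(
            Tensor(X), Tensor(np.zeros((n, n))), Tensor(Wq), Tensor(Wk),
            Tensor(Wv))
        without = position_aware_attention(
            Tensor(X), None, Tensor(Wq), Tensor(Wk), Tensor(Wv))
        assert np.allclose(with_zero.data, without.data)

    def test_uniform_attention_when_logits_constant(self):
        # zero queries make QK^T identically zero -> softmax uniform ->
        # each output row is the column-mean of V
        n, d = 4, 4
        V = RNG.normal(size=(n, d))
        out, w = attention_core(Tensor(np.zeros((n, d))),
                                Tensor(RNG.normal(size=(n, d))),
                                Tensor(V), None, d)
        assert np.allclose(w.data, 1.0 / n)
        assert np.allclose(out.data, V.mean(axis=0, keepdims=True), atol=1e-12)

    def test_attention_rows_sum_to_one(self):
        _, w = attention_core(Tensor(RNG.normal(size=(3, 7, 4))),
                              Tensor(RNG.normal(size=(3, 7, 4))),
                              Tensor(RNG.normal(size=(3, 7, 4))),
                              Tensor(RNG.normal(size=(3, 7, 7))), 4)
        assert np.allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_rejects_non_finite_input(self):
        X = np.zeros((2, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            attention_core(Tensor(X), Tensor(X), Tensor(X), None, 2)

    def test_gradient_check(self):
        n, d = 4, 4
        X = Parameter(RNG.normal(size=(n, d)))
        Wq = Parameter(RNG.normal(size=(d, d)))
        probe = Tensor(RNG.normal(size=(n, d)))
        Wk, Wv = Tensor(RNG.normal(size=(d, d))), Tensor(RNG.normal(size=(d, d)))
        bias = Tensor(RNG.normal(size=(n, n)))

        def build():
            return (position_aware_attention(X, bias, Wq, Wk, Wv) * probe).sum()

        loss = build()
        loss.backward()
        for p in (X, Wq):
            num = numerical_gradient(lambda: float(build().data), p.data)
            assert relative_error(p.grad, num) < 1e-4


class TestMultiHead:
    def test_single_head_identity_projection_degenerates(self):
        d = 8
        mha = MultiHeadAttention(d, 1, np.random.default_rng(0))
        mha.Wo.W.data = np.eye(d)
        X = RNG.normal(size=(1, 5, d))
        bias = RNG.normal(size=(1, 1, 5, 5))
        got = mha(Tensor(X), Tensor(bias))
        Wq, Wk, Wv = mha.head_params(0)
        single = position_aware_attention(
            Tensor(X[0]), Tensor(bias[0, 0]), Wq.detach(), Wk.detach(),
            Wv.detach())
        assert np.allclose(got.data[0], single.data, atol=1e-10)

    def test_default_head_count_output_shape(self):
        cfg = RunConfig()  # published defaults: 8 heads, d_model 512
        mha = MultiHeadAttention(cfg.d_model, cfg.n_heads,
                                 np.random.default_rng(0))
        out = mha(Tensor(RNG.normal(size=(1, 9, 512))),
                  Tensor(RNG.normal(size=(1, 8, 9, 9))))
        assert out.shape == (1, 9, 512)

    def test_permutation_equivariance(self):
        d, n = 8, 6
        mha = MultiHeadAttention(d, 2, np.random.default_rng(1))
        X = RNG.normal(size=(1, n, d))
        bias = RNG.normal(size=(1, 2, n, n))
        perm = np.random.default_rng(2).permutation(n)
        base = mha(Tensor(X), Tensor(bias)).data[0]
        permuted = mha(Tensor(X[:, perm]),
                       Tensor(bias[:, :, perm][:, :, :, perm])).data[0]
        assert np.allclose(permuted, base[perm], atol=1e-10)


class TestEncoder:
    def _cfg(self, **kw):
        return RunConfig.desk_scale(dropout=0.0, seed=0, **kw)

    def test_zero_layers_is_input_projection(self):
        cfg = self._cfg(n_layers=0)
        enc = GraphEncoder(5, cfg, np.random.default_rng(0))
        X = RNG.normal(size=(1, 3, 5))
        mask = np.ones((1, 3))
        out = enc(X, None, mask)
        want = X @ enc.input_proj.W.data + enc.input_proj.b.data
        assert np.allclose(out.data, want)

    def test_deterministic_without_dropout(self):
        cfg = self._cfg()
        enc = GraphEncoder(5, cfg, np.random.default_rng(0))
        X = RNG.normal(size=(2, 4, 5))
        mask = np.ones((2, 4))
        a = enc(X, None, mask).data
        b = enc(X, None, mask).data
        assert np.array_equal(a, b)

    def test_padded_rows_are_zero(self):
        cfg = self._cfg()
        enc = GraphEncoder(5, cfg, np.random.default_rng(0))
        mask = np.array([[1.0, 1.0, 0.0, 0.0]])
        out = enc(RNG.normal(size=(1, 4, 5)), None, mask).data
        assert np.all(out[0, 2:] == 0.0)

    def test_gcn_mode_requires_adjacency(self):
        cfg = self._cfg(gcn_baseline_mode=True)
        enc = GraphEncoder(5, cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="adjacency"):
            enc(RNG.normal(size=(1, 3, 5)), None, np.ones((1, 3)))

    def test_encoder_gradient_check(self):
        """Finite-difference vs analytic gradient through the full stack on
        a 4-atom instance."""
        cfg = RunConfig.desk_scale(dropout=0.0, n_layers=1, d_model=8,
                                   n_heads=2, ffn_mult=1)
        enc = GraphEncoder(5, cfg, np.random.default_rng(0))
        X = RNG.normal(size=(1, 4, 5))
        mask = np.ones((1, 4))
        probe = Tensor(RNG.normal(size=(1, 4, 8)))

        def build():
            return (enc(X, None, mask) * probe).sum()

        loss = build()
        loss.backward()
        for name, p in list(enc.named_parameters())[:6]:
            num = numerical_gradient(lambda: float(build().data), p.data)
            assert relative_error(p.grad, num) < 1e-4, name


class TestDiffPool:
    def test_single_cluster_assignment_is_all_ones(self):
        pool = DiffPool(4, 16, np.random.default_rng(0))
        H1 = Tensor(RNG.normal(size=(1, 5, 4)))
        A = np.ones((1, 5, 5)) - np.eye(5)
        res = pool(H1, A, np.ones((1, 5)), k=1)
        assert np.allclose(res.S2.data, 1.0)
        Z = pool.embed(H1).data
        assert np.allclose(res.H2.data[0, 0], Z[0].sum(axis=0), atol=1e-6)

    def test_assignment_rows_sum_to_one(self):
        pool = DiffPool(4, 16, np.random.default_rng(1))
        mask = np.array([[1.0] * 4 + [0.0] * 2])
        res = pool(Tensor(RNG.normal(size=(1, 6, 4))),
                   RNG.integers(0, 2, size=(1, 6, 6)).astype(float), mask,
                   k=3)
        sums = res.S2.data.sum(axis=-1)
        assert np.allclose(sums[0, :4], 1.0, atol=1e-6)
        assert np.allclose(sums[0, 4:], 0.0)

    def test_coarsened_adjacency_symmetric(self):
        pool = DiffPool(4, 16, np.random.default_rng(2))
        A = RNG.integers(0, 2, size=(6, 6)).astype(float)
        A = np.triu(A, 1) + np.triu(A, 1).T
        res = pool(Tensor(RNG.normal(size=(1, 6, 4))), A[None], np.ones((1, 6)),
                   k=3)
        assert np.abs(res.A2.data - res.A2.data.swapaxes(-1, -2)).max() < 1e-6

    def test_auto_cluster_count(self):
        assert auto_clusters(4) == 2
        assert auto_clusters(20) == 5
        assert auto_clusters(100) == 16


class TestGlobalAttentionPool:
    def test_single_cluster_returns_value_map(self):
        pool = GlobalAttentionPool(4, np.random.default_rng(0))
        H2 = Tensor(RNG.normal(size=(1, 1, 4)))
        h, gates = pool(H2)
        want = H2.data[0] @ pool.value.W.data + pool.value.b.data
        assert np.allclose(h.data, want, atol=1e-12)
        assert np.allclose(gates.data, 1.0)

    def test_identical_rows_independent_of_gates(self):
        pool = GlobalAttentionPool(4, np.random.default_rng(1))
        row = RNG.normal(size=4)
        H2 = Tensor(np.tile(row, (1, 5, 1)))
        h, gates = pool(H2)
        want = row @ pool.value.W.data + pool.value.b.data
        assert np.allclose(h.data[0], want, atol=1e-6)
        assert np.allclose(gates.data.sum(), 1.0, atol=1e-6)

    def test_hand_set_gate_logits(self):
        # H2 = [[1,0],[0,0]], identity gate-hidden and value maps, gate
        # weights chosen so cluster logits are (2, 0)
        pool = GlobalAttentionPool(2, np.random.default_rng(2))
        pool.gate_hidden.W.data = np.eye(2)
        pool.gate_hidden.b.data = np.zeros(2)
        pool.gate_out.W.data = np.array([[2.0 / np.tanh(1.0)], [0.0]])
        pool.gate_out.b.data = np.zeros(1)
        pool.value.W.data = np.eye(2)
        pool.value.b.data = np.zeros(2)
        H2 = Tensor(np.array([[[1.0, 0.0], [0.0, 0.0]]]))
        h, gates = pool(H2)
        w = np.exp([2.0, 0.0])
        w /= w.sum()
        assert np.allclose(gates.data[0], w, atol=1e-9)
        assert np.allclose(h.data[0], w[0] * np.array([1.0, 0.0]), atol=1e-9)


def test_normalized_adjacency_row_scaling():
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    A_hat = normalized_adjacency(A)
    # A + I with degree 2 on both nodes -> every entry 1/2
    assert np.allclose(A_hat, 0.5)
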