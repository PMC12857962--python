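"""SMILES tokenization, sequence encoding, cross-attention, gated fusion."""

import numpy as np
import pytest

from ddikit.autodiff import Tensor
from ddikit.config import RunConfig
from ddikit.fusion import (AdaptiveFusion, CrossAttention, SequenceEncoder,
                           TOKEN_TO_ID, tokenize)

RNG = np.random.default_rng(31)


class TestTokenizer:
    @pytest.mark.parametrize("smiles,n", [
        ("CCO", 3), ("CCl", 2), ("BrCC", 3), ("c1ccccc1", 8),
        ("C(=O)O", 6),
    ])
    def test_token_counts(self, smiles, n):
        assert len(tokenize(smiles)) == n

    def test_greedy_longest_match_chlorine(self):
        assert tokenize("CCl") == ["C", "Cl"]

    def test_unknown_character_maps_to_unk(self):
        assert tokenize("C~C") == ["C", "<unk>", "C"]


class TestSequenceEncoder:
    def _enc(self):
        return SequenceEncoder(RunConfig.desk_scale(dropout=0.0),
                               np.random.default_rng(0))

    def test_states_shape_and_padding_zeroed(self):
        enc = self._enc()
        ids = np.zeros((2, 6), dtype=np.intp)
        ids[0, :3] = [TOKEN_TO_ID["C"], TOKEN_TO_ID["C"], TOKEN_TO_ID["O"]]
        ids[1, :1] = [TOKEN_TO_ID["N"]]
        states, mask = enc(ids)
        assert states.shape == (2, 6, 32)
        assert np.all(states.data[0, 3:] == 0.0)
        assert mask.tolist() == [[1, 1, 1, 0, 0, 0], [1, 0, 0, 0, 0, 0]]

    def test_pooled_single_token_equals_its_state(self):
        enc = self._enc()
        out = enc.encode_one("C")
        assert np.allclose(out.pooled.data, out.token_states.data[0])

    def test_encode_one_token_count(self):
        assert self._enc().encode_one("CCO").token_states.shape[0] == 3


class TestCrossAttention:
    def test_single_token_gets_full_attention(self):
        ca = CrossAttention(8, 4, np.random.default_rng(0))
        H1 = Tensor(RNG.normal(size=(1, 5, 8)))
        tokens = Tensor(RNG.normal(size=(1, 1, 4)))
        _, alpha = ca(H1, tokens, np.ones((1, 1)))
        assert np.allclose(alpha.data, 1.0)

    def test_identical_tokens_make_output_alpha_independent(self):
        ca = CrossAttention(8, 4, np.random.default_rng(1))
        H1 = Tensor(RNG.normal(size=(1, 3, 8)))
        row = RNG.normal(size=4)
        tokens = Tensor(np.tile(row, (1, 6, 1)))
        out, _ = ca(H1, tokens, np.ones((1, 6)))
        want = H1.data + row @ ca.Wv.W.data
        assert np.allclose(out.data, want, atol=1e-6)

    def test_alpha_matches_double_loop_oracle(self):
        ca = CrossAttention(4, 4, np.random.default_rng(2))
        # identity projections expose the raw 3x2 score matrix
        ca.Wq.W.data = np.eye(4)
        ca.Wk.W.data = np.eye(4)
        H1 = Tensor(RNG.normal(size=(1, 3, 4)))
        tokens = Tensor(RNG.normal(size=(1, 2, 4)))
        _, alpha = ca(H1, tokens, np.ones((1, 2)))
        scores = H1.data[0] @ tokens.data[0].T
        for i in range(3):
            row = np.exp(scores[i] - scores[i].max())
            row /= row.sum()
            assert np.abs(alpha.data[0, i] - row).max() < 1e-6

    def test_alpha_rows_sum_to_one_under_padding(self):
        ca = CrossAttention(8, 4, np.random.default_rng(3))
        mask = np.array([[1.0, 1.0, 1.0, 0.0]])
        _, alpha = ca(Tensor(RNG.normal(size=(1, 5, 8))),
                      Tensor(RNG.normal(size=(1, 4, 4))), mask)
        assert np.allclose(alpha.data.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(alpha.data[..., 3] == 0.0)


class TestAdaptiveFusion:
    def test_identical_modalities_fixed_point(self):
        fuse = AdaptiveFusion(4, 4, np.random.default_rng(0))
        fuse.project_seq.W.data = np.eye(4)
        fuse.project_seq.b.data = np.zeros(4)
        v = Tensor(RNG.normal(size=(2, 4)))
        _, h = fuse(v, v)
        assert np.allclose(h.data, v.data, atol=1e-12)

    def test_hand_set_gate_mixes_quarter(self):
        fuse = AdaptiveFusion(2, 2, np.random.default_rng(1))
        fuse.project_seq.W.data = np.eye(2)
        fuse.project_seq.b.data = np.zeros(2)
        # force the gate to lambda = 0.25 regardless of input
        fuse.gate_fc1.W.data = np.zeros_like(fuse.gate_fc1.W.data)
        fuse.gate_fc1.b.data = np.zeros_like(fuse.gate_fc1.b.data)
        fuse.gate_fc2.W.data = np.zeros_like(fuse.gate_fc2.W.data)
        fuse.gate_fc2.b.data = np.array([np.log(0.25 / 0.75)])
        lam, h = fuse(Tensor([[1.0, 0.0]]), Tensor([[0.0, 1.0]]))
        assert np.allclose(lam.data, 0.25, atol=1e-12)
        assert np.allclose(h.data, [[0.25, 0.75]], atol=1e-12)

    def test_saturated_gate_recovers_graph_only_limit(self):
        fuse = AdaptiveFusion(2, 2, np.random.default_rng(2))
        fuse.gate_fc2.b.data = np.array([50.0])  # sigmoid -> 1
        fuse.gate_fc2.W.data = np.zeros_like(fuse.gate_fc2.W.data)
        g = Tensor([[3.0, -1.0]])
        lam, h = fuse(g, Tensor([[9.9, 9.9]]))
        assert np.allclose(h.data, g.data)

    def test_lambda_strictly_inside_unit_interval(self):
        fuse = AdaptiveFusion(8, 4, np.random.default_rng(3))
        lam, _ = fuse(Tensor(RNG.normal(size=(10, 8))),
                      Tensor(RNG.normal(size=(10, 4))))
        assert np.all(lam.data > 0.0) and np.all(lam.data < 1.0)

    def test_non_adaptive_mode_uses_half(self):
        fuse = AdaptiveFusion(2, 2, np.random.default_rng(4))
        lam, _ = fuse(Tensor([[1.0, 0.0]]), Tensor([[0.0, 1.0]]),
                      adaptive=False)
        assert np.all(lam.data == 0.5)

    def test_fusion_continuous_in_gate_weights(self):
        fuse = AdaptiveFusion(4, 4, np.random.default_rng(5))
        g = Tensor(RNG.normal(size=(1, 4)))
        s = Tensor(RNG.normal(size=(1, 4)))
        _, h0 = fuse(g, s)
        eps = 1e-5
        fuse.gate_fc2.b.data += eps
        _, h1 = fuse(g, s)
        assert np.abs(h1.data - h0.data).max() < 10 * eps
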