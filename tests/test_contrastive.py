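"""Contrastive objective: closed forms, hard mining, and trainability."""

import math

import numpy as np
import pytest

from ddikit.autodiff import Parameter, Tensor
from ddikit.config import RunConfig
from ddikit.contrastive import (EmbeddingBatch, batch_contrastive_loss,
                                contrastive_loss, hard_contrastive_loss,
                                l2_normalize, mine_hard_negatives)
from ddikit.nn import AdamW

RNG = np.random.default_rng(23)


def cfg(**kw):
    return RunConfig(**{"temperature": 0.1, **kw})


def batch_of(Z, Zp):
    return EmbeddingBatch(Z=Tensor(Z), Z_plus=Tensor(Zp))


def unit_rows(n, d, rng):
    Z = rng.normal(size=(n, d))
    return Z / np.linalg.norm(Z, axis=1, keepdims=True)


class TestClosedForms:
    @pytest.mark.parametrize("B", [2, 4, 8])
    def test_identical_embeddings_with_positive_mode(self, B):
        # all similarities 1 -> denominator B * exp(1/tau) -> loss log(B)
        v = np.zeros((B, 4))
        v[:, 0] = 1.0
        loss = contrastive_loss(batch_of(v, v),
                                cfg(denominator_mode="with_positive"))
        assert abs(loss.item() - math.log(B)) < 1e-6

    @pytest.mark.parametrize("B", [2, 4, 8])
    def test_identical_embeddings_literal_mode(self, B):
        v = np.zeros((B, 4))
        v[:, 0] = 1.0
        loss = contrastive_loss(batch_of(v, v), cfg(denominator_mode="literal"))
        assert abs(loss.item() - math.log(B - 1)) < 1e-6

    def test_orthogonal_negatives_two_term_form(self):
        # z+ = z, the single negative orthogonal, tau = 0.1:
        # loss = log(1 + exp((0 - 1)/0.1)) = log(1 + e^-10)
        Z = np.eye(2, 4)
        loss = contrastive_loss(batch_of(Z, Z), cfg(temperature=0.1))
        assert abs(loss.item() - math.log(1 + math.exp(-10))) < 1e-9
        # sharper temperature drives the loss toward zero
        sharper = contrastive_loss(batch_of(Z, Z), cfg(temperature=0.02))
        assert sharper.item() < loss.item()

    def test_hard_identical_embeddings_k1_gives_log2(self):
        v = np.tile([1.0, 0.0], (4, 1))
        loss = hard_contrastive_loss(batch_of(v, v), cfg(hard_negative_k=1))
        assert abs(loss.item() - math.log(2)) < 1e-6


class TestHardMining:
    def test_full_k_equals_with_positive_loss(self):
        for trial in range(100):
            rng = np.random.default_rng(trial)
            B = int(rng.integers(3, 9))
            Z = unit_rows(B, 6, rng)
            Zp = unit_rows(B, 6, rng)
            full = contrastive_loss(batch_of(Z, Zp),
                                    cfg(denominator_mode="with_positive"))
            hard = hard_contrastive_loss(batch_of(Z, Zp),
                                         cfg(hard_negative_k=B - 1))
            assert abs(full.item() - hard.item()) < 1e-12

    def test_near_collinear_negative_selected(self):
        anchor = np.array([1.0, 0.0, 0.0])
        near = np.array([0.99, 0.1, 0.0])
        near /= np.linalg.norm(near)
        Z = np.stack([anchor, near, [0.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        idx = mine_hard_negatives(batch_of(Z, Z), k=1)
        assert idx[0, 0] == 1

    def test_permutation_consistency(self):
        rng = np.random.default_rng(5)
        Z = unit_rows(6, 4, rng)
        idx = mine_hard_negatives(batch_of(Z, Z), k=2)
        perm = rng.permutation(6)
        idx_p = mine_hard_negatives(batch_of(Z[perm], Z[perm]), k=2)
        for i in range(6):
            # permuted row j holds original row perm[j]
            assert sorted(perm[idx_p[i]]) == sorted(idx[perm[i]])

    def test_tie_break_by_ascending_index(self):
        Z = np.tile([1.0, 0.0], (4, 1))  # all similarities tie at 1
        idx = mine_hard_negatives(batch_of(Z, Z), k=2)
        assert idx[0].tolist() == [1, 2]
        assert idx[3].tolist() == [0, 1]

    def test_oversized_k_clamps_with_warning(self, caplog):
        Z = unit_rows(3, 4, np.random.default_rng(0))
        idx = mine_hard_negatives(batch_of(Z, Z), k=10)
        assert idx.shape == (3, 2)


class TestProperties:
    def test_batch_of_one_rejected(self):
        Z = np.ones((1, 3))
        with pytest.raises(ValueError):
            contrastive_loss(batch_of(Z, Z), cfg())

    def test_loss_decreases_in_positive_similarity(self):
        # finite-difference monotonicity probe: raise sim(z, z+) -> loss falls
        rng = np.random.default_rng(7)
        Z = unit_rows(5, 8, rng)
        base_dir = unit_rows(5, 8, rng)
        losses = []
        for t in (0.0, 0.3, 0.7, 1.0):
            Zp = l2_normalize(Tensor((1 - t) * base_dir + t * Z)).data
            losses.append(hard_contrastive_loss(
                batch_of(Z, Zp), cfg(hard_negative_k=2)).item())
        assert all(a >= b for a, b in zip(losses, losses[1:]))

    def test_dispatch_honors_hard_mining_switch(self):
        rng = np.random.default_rng(8)
        Z, Zp = unit_rows(6, 4, rng), unit_rows(6, 4, rng)
        soft = batch_contrastive_loss(batch_of(Z, Zp),
                                      cfg(use_hard_mining=False))
        hard = batch_contrastive_loss(batch_of(Z, Zp),
                                      cfg(use_hard_mining=True,
                                          hard_negative_k=2))
        assert soft.item() != pytest.approx(hard.item())

    def test_gradient_descent_aligns_positives(self):
        """200 optimizer steps on raw embeddings: loss falls on >=95% of
        steps and positives end up more similar than negatives."""
        rng = np.random.default_rng(9)
        Z = Parameter(rng.normal(size=(16, 32)))
        Zp = Parameter(rng.normal(size=(16, 32)))
        opt = AdamW([Z, Zp], lr=5e-2)
        c = cfg()
        losses = []
        for _ in range(200):
            batch = EmbeddingBatch(Z=l2_normalize(Z), Z_plus=l2_normalize(Zp))
            loss = contrastive_loss(batch, c)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        drops = sum(b < a for a, b in zip(losses, losses[1:]))
        assert drops >= 0.95 * (len(losses) - 1)
        Zn = l2_normalize(Z).data
        Zpn = l2_normalize(Zp).data
        pos_cos = np.sum(Zn * Zpn, axis=1).mean()
        neg_cos = (Zn @ Zn.T)[~np.eye(16, dtype=bool)].mean()
        assert pos_cos > neg_cos
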