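"""Chemically-constrained augmentation operators."""

import math

import numpy as np
import pytest

from conftest import graph_from_smiles
from ddikit.augmentation import (OPERATORS, apply_operator, atom_mask,
                                 bond_perturb, build_scaffold_pool,
                                 extract_scaffold, importance, make_views,
                                 sample_view, scaffold_hop, subgraph_sample)
from ddikit.chem import scaffold_atoms
from ddikit.config import RunConfig
from ddikit.mol_io import validate_graph


def cfg(**kw):
    return RunConfig.desk_scale(seed=0, **kw)


class TestImportance:
    def test_ring_carbon_outranks_terminal_methyl(self):
        benzene = graph_from_smiles("c1ccccc1")
        toluene = graph_from_smiles("Cc1ccccc1")
        assert importance(benzene, 0) >= importance(toluene, 0)

    def test_isolated_carbon_scores_floor(self):
        g = graph_from_smiles("C")
        assert importance(g, 0) == 0.0

    def test_carboxyl_oxygen_outranks_chain_carbon(self):
        g = graph_from_smiles("CC(=O)O")
        assert importance(g, 3) > importance(g, 0)

    def test_invalid_index_raises(self):
        with pytest.raises(IndexError):
            importance(graph_from_smiles("CC"), 5)


class TestAtomMask:
    def test_zero_ratio_is_identity(self):
        g = graph_from_smiles("CCCCCC")
        v = atom_mask(g, cfg(mask_ratio=0.0), np.random.default_rng(0))
        assert not v.view.mask_flags.any()

    def test_mask_count_floor_arithmetic(self):
        # 20 atoms at the published mask ratio 0.15 -> exactly 3 masked
        g = graph_from_smiles("C" * 20)
        v = atom_mask(g, cfg(mask_ratio=0.15), np.random.default_rng(1))
        assert g.n_atoms == 20
        assert v.view.mask_flags.sum() == math.floor(0.15 * 20) == 3

    def test_masked_atoms_below_threshold(self):
        g = graph_from_smiles("CCCCc1ccccc1C(=O)O")
        c = cfg(mask_ratio=0.3)
        v = atom_mask(g, c, np.random.default_rng(2))
        for idx in np.flatnonzero(v.view.mask_flags):
            assert importance(g, int(idx)) < c.importance_threshold

    def test_topology_unchanged_in_token_mode(self):
        g = graph_from_smiles("CCCCCCCC")
        v = atom_mask(g, cfg(mask_ratio=0.25), np.random.default_rng(3))
        assert v.view.n_atoms == g.n_atoms
        assert v.view.n_bonds == g.n_bonds

    def test_delete_mode_removes_atoms(self):
        g = graph_from_smiles("CCCCCCCC")
        v = atom_mask(g, cfg(mask_ratio=0.25, mask_mode="delete"),
                      np.random.default_rng(4))
        assert v.view.n_atoms == g.n_atoms - 2
        validate_graph(v.view)


class TestBondPerturb:
    def test_zero_ratio_is_identity(self):
        g = graph_from_smiles("CCO")
        v = bond_perturb(g, cfg(perturb_ratio=0.0), np.random.default_rng(0))
        assert [b.order for b in v.view.bonds] == [b.order for b in g.bonds]

    def test_perturbed_views_stay_valence_valid(self, random_graphs):
        rng = np.random.default_rng(5)
        c = cfg(perturb_ratio=0.3)
        for g in random_graphs:
            for _ in range(3):
                validate_graph(bond_perturb(g, c, rng).view)

    def test_aromatic_bonds_never_perturbed(self):
        g = graph_from_smiles("c1ccccc1")
        v = bond_perturb(g, cfg(perturb_ratio=1.0), np.random.default_rng(6))
        assert all(b.order == 1.5 for b in v.view.bonds)

    def test_single_bond_between_saturated_carbons_resamples_validly(self):
        # "CC": both carbons carry 3 implicit H, which shrink to admit any
        # order in {1,2,3}; every sampled outcome must revalidate
        g = graph_from_smiles("CC")
        seen = set()
        for s in range(30):
            v = bond_perturb(g, cfg(perturb_ratio=1.0),
                             np.random.default_rng(s))
            validate_graph(v.view)
            seen.add(v.view.bonds[0].order)
        assert seen <= {1.0, 2.0, 3.0} and len(seen) > 1


class TestSubgraphSample:
    def test_full_ratio_keeps_connected_component(self):
        g = graph_from_smiles("CCCCCC")
        v = subgraph_sample(g, cfg(sample_ratio=1.0), np.random.default_rng(0))
        assert v.view.n_atoms == g.n_atoms

    def test_ceiling_size_and_connectivity(self):
        # published sample ratio 0.75 on an 8-atom chain -> ceil(6) = 6 atoms
        g = graph_from_smiles("CCCCCCCC")
        v = subgraph_sample(g, cfg(sample_ratio=0.75),
                            np.random.default_rng(1))
        assert v.view.n_atoms == math.ceil(0.75 * 8) == 6
        # connectivity: n-1 bonds for a tree subgraph of a chain
        assert v.view.n_bonds == v.view.n_atoms - 1

    def test_induced_subgraph_keeps_internal_bonds(self):
        g = graph_from_smiles("CC(N)c1ccccc1C(=O)O")
        v = subgraph_sample(g, cfg(sample_ratio=0.7), np.random.default_rng(2))
        kept = v.provenance["kept"]
        index = {old: new for new, old in enumerate(kept)}
        expected = {(min(index[b.i], index[b.j]), max(index[b.i], index[b.j]))
                    for b in g.bonds if b.i in index and b.j in index}
        got = {(min(b.i, b.j), max(b.i, b.j)) for b in v.view.bonds}
        assert got == expected


class TestScaffoldHop:
    def test_zero_probability_is_identity(self):
        g = graph_from_smiles("Cc1ccccc1")
        pool = build_scaffold_pool([graph_from_smiles("Cc1ccncc1")])
        v = scaffold_hop(g, cfg(hop_probability=0.0), pool,
                         np.random.default_rng(0))
        assert not v.provenance["hopped"]

    def test_toluene_to_pyridine_scaffold(self):
        toluene = graph_from_smiles("Cc1ccccc1")
        pool = build_scaffold_pool([graph_from_smiles("Cc1ccncc1")])
        v = scaffold_hop(toluene, cfg(hop_probability=1.0), pool,
                         np.random.default_rng(1))
        assert v.provenance["hopped"]
        assert v.view.n_atoms == 7  # methyl + 6-ring
        assert any(a.symbol == "N" for a in v.view.atoms)
        validate_graph(v.view)

    def test_side_chain_atom_count_conserved(self, random_graphs):
        pool = build_scaffold_pool(random_graphs)
        rng = np.random.default_rng(2)
        c = cfg(hop_probability=1.0)
        hops = 0
        for g in random_graphs[:30]:
            core = scaffold_atoms(g)
            if not core:
                continue
            v = scaffold_hop(g, c, pool, rng)
            if not v.provenance["hopped"]:
                continue
            hops += 1
            new_core = scaffold_atoms(v.view)
            assert v.view.n_atoms - len(new_core) == g.n_atoms - len(core)
            validate_graph(v.view)
        assert hops >= 3

    def test_acyclic_molecule_is_identity(self):
        g = graph_from_smiles("CCCCO")
        v = scaffold_hop(g, cfg(hop_probability=1.0), [],
                         np.random.default_rng(3))
        assert not v.provenance["hopped"]

    def test_extract_scaffold_attachment_points(self):
        scaf = extract_scaffold(graph_from_smiles("Cc1ccc(N)cc1"))
        assert scaf.graph.n_atoms == 6
        assert len(scaf.attachment_points) == 2


class TestEnsemble:
    def test_degenerate_weights_pick_single_operator(self):
        g = graph_from_smiles("CCCCCCCCCC")
        c = cfg(ensemble_weights=(1.0, 0.0, 0.0, 0.0))
        v1, v2 = make_views(g, c, np.random.default_rng(0))
        assert v1.operator == v2.operator == "atom_mask"

    def test_fixed_seed_reproducible(self):
        g = graph_from_smiles("CC(N)c1ccccc1C(=O)O")
        c = cfg()
        a1, a2 = make_views(g, c, np.random.default_rng(9))
        b1, b2 = make_views(g, c, np.random.default_rng(9))
        assert a1.operator == b1.operator and a2.operator == b2.operator
        assert a1.provenance == b1.provenance

    def test_operator_frequencies_within_binomial_bound(self):
        """10,000 uniform draws: each operator within 3 sigma of 2,500."""
        g = graph_from_smiles("CCCC")  # tiny molecule keeps draws cheap
        c = cfg(ensemble_weights=(0.25, 0.25, 0.25, 0.25))
        rng = np.random.default_rng(13)
        counts = {op: 0 for op in OPERATORS}
        for _ in range(10_000):
            counts[sample_view(g, c, rng, []).operator] += 1
        sigma = math.sqrt(10_000 * 0.25 * 0.75)
        for op in OPERATORS:
            assert abs(counts[op] - 2500) <= 3 * sigma, counts


def test_all_operators_identity_at_zero_intensity(random_graphs):
    c = cfg(mask_ratio=0.0, perturb_ratio=0.0, sample_ratio=1.0,
            hop_probability=0.0)
    rng = np.random.default_rng(0)
    for g in random_graphs[:10]:
        for op in OPERATORS:
            v = apply_operator(op, g, c, rng, [])
            assert v.view.n_atoms == g.n_atoms
            assert v.view.n_bonds == g.n_bonds
            assert not v.view.mask_flags.any()
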