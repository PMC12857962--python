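"""Shared fixtures: synthetic data, desk-scale configs, numeric helpers."""

from __future__ import annotations

import numpy as np
import pytest

from ddikit.config import RunConfig
from ddikit.mol_io import (AtomRecord, BondRecord, MolecularGraph, featurize,
                           parse_smiles)
from ddikit.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """60 drugs / 240 balanced pairs, noise-free, fixed seed."""
    return generate_dataset(GeneratorConfig(n_drugs=60, n_pairs=240, seed=101))


@pytest.fixture(scope="session")
def random_graphs(small_dataset):
    """Parsed, featurized graphs of the synthetic drugs."""
    return [small_dataset.drugs.graph(d) for d in small_dataset.drugs.ids()]


@pytest.fixture
def desk_cfg():
    return RunConfig.desk_scale(seed=0, dropout=0.0)


def graph_from_smiles(smiles: str) -> MolecularGraph:
    return featurize(parse_smiles(smiles))


def permute_graph(graph: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    """Relabel atoms by ``perm``: new index perm[i] holds old atom i."""
    n = graph.n_atoms
    inv = np.empty(n, dtype=int)
    inv[perm] = np.arange(n)
    atoms = [graph.atoms[inv[k]] for k in range(n)]
    bonds = [BondRecord(int(perm[b.i]), int(perm[b.j]), b.order, b.in_ring)
             for b in graph.bonds]
    out = MolecularGraph(atoms=atoms, bonds=bonds, smiles=graph.smiles,
                         mask_flags=graph.mask_flags[inv].copy())
    featurize(out)
    return out


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar-valued f with respect to x
    (mutates and restores x in place)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def relative_error(analytic: np.ndarray, numeric: np.ndarray) -> float:
    scale = max(np.abs(numeric).max(), np.abs(analytic).max(), 1e-8)
    return float(np.abs(analytic - numeric).max() / scale)
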