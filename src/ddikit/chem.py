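"""Shared chemistry utilities: functional-group detection and Murcko scaffolds.

The functional-group table covers the pharmacologically salient substructures
this package cares about (carboxyl, amine, hydroxyl, carbonyl, sulfonyl,
halogen-on-carbon, aromatic ring).  Matching runs RDKit SMARTS queries on a
mol rebuilt from the package's own graph type.

Murcko scaffolds (ring systems plus the linkers joining them) are computed by
iterative pruning of non-ring terminal atoms, directly on the graph — no
external scaffold library is involved.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from rdkit import Chem

from .mol_io import MolecularGraph, to_rdkit

FUNCTIONAL_GROUP_SMARTS: dict[str, str] = {
    "carboxyl": "[CX3](=O)[OX2H1,OX1-]",
    "amine": "[NX3;H2,H1,H0;!$(N=*);!$(N[CX3]=[OX1]);!a]",
    "hydroxyl": "[OX2H][#6;!$([CX3]=[OX1])]",
    "carbonyl": "[CX3]=[OX1]",
    "sulfonyl": "[#16X4](=[OX1])(=[OX1])",
    "halogen_on_carbon": "[F,Cl,Br,I][#6]",
    "aromatic_ring": "a1aaaaa1",
}


@lru_cache(maxsize=None)
def _compiled(smarts: str):
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:  # pragma: no cover - table is static
        raise ValueError(f"bad SMARTS {smarts!r}")
    return patt


def functional_groups(graph: MolecularGraph) -> dict[str, list[tuple[int, ...]]]:
    """All functional-group matches, name -> list of atom-index tuples.

    Cached on the graph object (topology is immutable once parsed; augmented
    views are new objects and get their own cache).
    """
    cached = getattr(graph, "_fg_cache", None)
    if cached is not None:
        return cached
    mol = to_rdkit(graph)
    out: dict[str, list[tuple[int, ...]]] = {}
    for name, smarts in FUNCTIONAL_GROUP_SMARTS.items():
        matches = mol.GetSubstructMatches(_compiled(smarts))
        if matches:
            out[name] = [tuple(m) for m in matches]
    graph._fg_cache = out
    return out


def functional_group_atoms(graph: MolecularGraph) -> set[int]:
    """Union of atoms participating in any functional-group match."""
    atoms: set[int] = set()
    for matches in functional_groups(graph).values():
        for m in matches:
            atoms.update(m)
    return atoms


def has_group(graph: MolecularGraph, name: str) -> bool:
    return name in functional_groups(graph)


# ---------------------------------------------------------------------------
# Murcko scaffolds
# ---------------------------------------------------------------------------

def ring_atoms(graph: MolecularGraph) -> set[int]:
    atoms: set[int] = set()
    for b in graph.bonds:
        if b.in_ring:
            atoms.add(b.i)
            atoms.add(b.j)
    return atoms


def scaffold_atoms(graph: MolecularGraph) -> set[int]:
    """Murcko scaffold atom set: iteratively prune non-ring terminal atoms.

    What remains is exactly the ring systems plus linkers; an acyclic
    molecule has an empty scaffold.
    """
    if not ring_atoms(graph):
        return set()
    alive = set(range(graph.n_atoms))
    in_ring = ring_atoms(graph)
    adj = {i: set() for i in alive}
    for b in graph.bonds:
        adj[b.i].add(b.j)
        adj[b.j].add(b.i)
    changed = True
    while changed:
        changed = False
        for a in sorted(alive):
            if a in in_ring:
                continue
            deg = len(adj[a] & alive)
            if deg <= 1:
                alive.discard(a)
                changed = True
    return alive


def scaffold_smiles(graph: MolecularGraph) -> str:
    """Canonical SMILES of the Murcko scaffold ('' for acyclic molecules)."""
    keep = scaffold_atoms(graph)
    if not keep:
        return ""
    mol = to_rdkit(graph)
    rw = Chem.RWMol(mol)
    for idx in sorted(set(range(graph.n_atoms)) - keep, reverse=True):
        rw.RemoveAtom(idx)
    sub = rw.GetMol()
    try:
        Chem.SanitizeMol(sub)
    except Exception:
        sub.UpdatePropertyCache(strict=False)
    return Chem.MolToSmiles(sub)


def connected_components(graph: MolecularGraph,
                         subset: set[int] | None = None) -> list[set[int]]:
    """Connected components of the induced subgraph on ``subset`` (or all)."""
    nodes = set(range(graph.n_atoms)) if subset is None else set(subset)
    adj = {i: set() for i in nodes}
    for b in graph.bonds:
        if b.i in nodes and b.j in nodes:
            adj[b.i].add(b.j)
            adj[b.j].add(b.i)
    comps: list[set[int]] = []
    left = set(nodes)
    while left:
        start = min(left)
        comp = {start}
        frontier = [start]
        while frontier:
            cur = frontier.pop()
            for nb in adj[cur]:
                if nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(comp)
        left -= comp
    return comps
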