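"""Chemically-constrained molecular augmentation for contrastive learning.

Four operators, each emitting a valence-valid view of the input graph:

* **atom masking** — atoms whose chemical-importance score falls below a
  threshold are candidates; a mask_ratio fraction of them have their feature
  rows replaced by a learned mask token (topology unchanged).  A delete mode
  exists behind ``mask_mode="delete"``.
* **bond perturbation** — a perturb_ratio fraction of non-aromatic bonds are
  re-typed, the new order sampled uniformly from the orders that keep both
  endpoints within the valence table.
* **subgraph sampling** — a connected induced subgraph grown breadth-first
  from a functional-group seed to ceil(sample_ratio * n) atoms.
* **scaffold hopping** — with probability hop_probability the molecule's
  Murcko scaffold is swapped for a pool scaffold with the same number of
  attachment points, side chains reattached.

The importance score is a fixed convex combination of chemically salient
indicators: 0.4 * ring membership + 0.3 * heteroatom + 0.2 * functional-group
membership + 0.1 * min(degree, 4) / 4.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .chem import (connected_components, functional_group_atoms,
                   functional_groups, scaffold_atoms)
from .config import RunConfig
from .mol_io import (AtomRecord, BondRecord, MolecularGraph, check_valence,
                     featurize, to_smiles, validate_graph, VALENCE_TABLE)

logger = logging.getLogger(__name__)

OPERATORS = ("atom_mask", "bond_perturb", "subgraph_sample", "scaffold_hop")


def _reserialize(view: MolecularGraph) -> None:
    """Refresh ``view.smiles`` so the sequence pathway sees the augmented
    structure (masked atoms serialize as ``*``).  Keeps the source string
    when serialization fails."""
    try:
        view.smiles = to_smiles(view, masked_as_dummy=True)
    except Exception:  # pragma: no cover - RDKit rebuild edge cases
        logger.info("view re-serialization failed; keeping source SMILES")


def _copy_caches(src: MolecularGraph, dst: MolecularGraph,
                 spatial: bool = True, tokens: bool = False) -> None:
    """Carry over per-graph caches that remain valid for the view."""
    if spatial and hasattr(src, "_spatial_cache"):
        dst._spatial_cache = src._spatial_cache
    if hasattr(src, "_fg_cache"):
        dst._fg_cache = src._fg_cache
    if tokens and hasattr(src, "_token_cache"):
        dst._token_cache = src._token_cache


def _identity_view(graph: MolecularGraph, operator: str,
                   provenance: dict) -> AugmentedView:
    view = graph.copy()
    _copy_caches(graph, view, spatial=True, tokens=True)
    return AugmentedView(view, operator, provenance)


@dataclass
class AugmentedView:
    view: MolecularGraph
    operator: str
    provenance: dict = field(default_factory=dict)


def importance(graph: MolecularGraph, atom: int,
               fg_atoms: set[int] | None = None) -> float:
    """Deterministic chemical-importance score in [0, 1].

    Higher for ring members, heteroatoms, and functional-group members.
    """
    if not (0 <= atom < graph.n_atoms):
        raise IndexError(f"atom index {atom} out of range")
    if fg_atoms is None:
        fg_atoms = functional_group_atoms(graph)
    rec = graph.atoms[atom]
    in_ring = any(b.in_ring and atom in (b.i, b.j) for b in graph.bonds)
    hetero = rec.symbol != "C"
    in_fg = atom in fg_atoms
    deg = min(rec.degree, 4) / 4.0
    return 0.4 * in_ring + 0.3 * hetero + 0.2 * in_fg + 0.1 * deg


def atom_mask(graph: MolecularGraph, config: RunConfig,
              rng: np.random.Generator) -> AugmentedView:
    """Mask low-importance atoms (feature-token replacement by default)."""
    n = graph.n_atoms
    fg = functional_group_atoms(graph)
    candidates = [i for i in range(n)
                  if importance(graph, i, fg) < config.importance_threshold]
    want = math.floor(config.mask_ratio * n)
    if want == 0 or not candidates:
        if want > 0:
            logger.info("atom_mask: no candidates below threshold; identity")
        return _identity_view(graph, "atom_mask", {"masked": []})
    chosen = sorted(rng.choice(candidates, size=min(want, len(candidates)),
                               replace=False).tolist())
    if config.mask_mode == "delete":
        keep = [i for i in range(n) if i not in set(chosen)]
        view = _induced_subgraph(graph, keep)
        return AugmentedView(view, "atom_mask",
                             {"masked": chosen, "mode": "delete"})
    view = graph.copy()
    view.mask_flags = view.mask_flags.copy()
    view.mask_flags[chosen] = True
    _copy_caches(graph, view)  # topology unchanged
    _reserialize(view)
    return AugmentedView(view, "atom_mask", {"masked": chosen, "mode": "token"})


def _valid_orders(graph: MolecularGraph, bond_idx: int) -> list[float]:
    """Bond orders (1, 2, 3) keeping BOTH endpoints within the valence table;
    implicit hydrogens shrink to absorb added order."""
    b = graph.bonds[bond_idx]
    orders = []
    for order in (1.0, 2.0, 3.0):
        extra = order - b.order
        if check_valence(graph, b.i, extra) and check_valence(graph, b.j, extra):
            orders.append(order)
    return orders


def bond_perturb(graph: MolecularGraph, config: RunConfig,
                 rng: np.random.Generator) -> AugmentedView:
    """Re-type a perturb_ratio fraction of bonds within valence limits.

    Aromatic bonds are excluded.  A bond with no alternative valid order is
    left unchanged.
    """
    m = graph.n_bonds
    want = math.floor(config.perturb_ratio * m)
    changed: list[tuple[int, float, float]] = []
    eligible = [k for k, b in enumerate(graph.bonds) if b.order != 1.5]
    if want == 0 or not eligible:
        return _identity_view(graph, "bond_perturb", {"changed": changed})
    view = graph.copy()
    picked = rng.choice(eligible, size=min(want, len(eligible)),
                        replace=False).tolist()
    for k in sorted(picked):
        orders = _valid_orders(view, k)
        if not orders:
            logger.info("bond_perturb: bond %d has no valid order; unchanged", k)
            continue
        new_order = float(rng.choice(orders))
        old = view.bonds[k]
        if new_order != old.order:
            # implicit H counts shrink/grow with the order change
            delta = new_order - old.order
            view.bonds[k] = BondRecord(old.i, old.j, new_order, old.in_ring)
            for endpoint in (old.i, old.j):
                rec = view.atoms[endpoint]
                new_h = max(0, int(round(rec.implicit_h - delta)))
                view.atoms[endpoint] = AtomRecord(
                    rec.symbol, rec.formal_charge, rec.degree, rec.aromatic,
                    new_h)
            changed.append((k, old.order, new_order))
    validate_graph(view)
    featurize(view)
    # connectivity is untouched, so unit-weight distances still hold
    if getattr(graph, "_spatial_cache", (("",),))[0][0] == "unit":
        _copy_caches(graph, view, spatial=True)
    if changed:
        _reserialize(view)
    return AugmentedView(view, "bond_perturb", {"changed": changed})


def _induced_subgraph(graph: MolecularGraph, keep: list[int]) -> MolecularGraph:
    """Induced subgraph on ``keep`` with atoms reindexed in given order."""
    index = {old: new for new, old in enumerate(keep)}
    atoms = []
    for old in keep:
        rec = graph.atoms[old]
        new_deg = sum(1 for b in graph.bonds
                      if (b.i == old and b.j in index)
                      or (b.j == old and b.i in index))
        atoms.append(AtomRecord(rec.symbol, rec.formal_charge, new_deg,
                                rec.aromatic, rec.implicit_h))
    bonds = [BondRecord(index[b.i], index[b.j], b.order, b.in_ring)
             for b in graph.bonds if b.i in index and b.j in index]
    sub = MolecularGraph(atoms=atoms, bonds=bonds, smiles=graph.smiles,
                         mask_flags=graph.mask_flags[keep].copy())
    featurize(sub)
    return sub


def subgraph_sample(graph: MolecularGraph, config: RunConfig,
                    rng: np.random.Generator) -> AugmentedView:
    """Connected induced subgraph grown breadth-first from a functional-group
    seed (random atom if the molecule has no detected group)."""
    n = graph.n_atoms
    target = min(n, math.ceil(config.sample_ratio * n))
    groups = functional_groups(graph)
    if groups:
        names = sorted(groups)
        name = names[int(rng.integers(len(names)))]
        match = groups[name][int(rng.integers(len(groups[name])))]
        seed = int(match[int(rng.integers(len(match)))])
    else:
        name, seed = None, int(rng.integers(n))
    adj = {i: [] for i in range(n)}
    for b in graph.bonds:
        adj[b.i].append(b.j)
        adj[b.j].append(b.i)
    visited = [seed]
    chosen = {seed}
    frontier = [seed]
    while frontier and len(chosen) < target:
        nxt: list[int] = []
        for cur in frontier:
            for nb in sorted(adj[cur]):
                if nb not in chosen and len(chosen) < target:
                    chosen.add(nb)
                    visited.append(nb)
                    nxt.append(nb)
        frontier = nxt
    view = _induced_subgraph(graph, sorted(chosen))
    validate_graph(view)
    if len(chosen) < n:
        _reserialize(view)
    return AugmentedView(view, "subgraph_sample",
                         {"seed": seed, "seed_group": name,
                          "kept": sorted(chosen)})


# ---------------------------------------------------------------------------
# Scaffold hopping
# ---------------------------------------------------------------------------

@dataclass
class Scaffold:
    """A Murcko scaffold as a standalone graph plus its attachment points
    (scaffold atoms that carried side chains in the source molecule)."""
    graph: MolecularGraph
    attachment_points: tuple[int, ...]
    source_smiles: str


def extract_scaffold(graph: MolecularGraph) -> Scaffold | None:
    """The molecule's Murcko scaffold, or None for acyclic molecules."""
    core = scaffold_atoms(graph)
    if not core:
        return None
    keep = sorted(core)
    index = {old: new for new, old in enumerate(keep)}
    attach = sorted({index[b.i] if b.i in core else index[b.j]
                     for b in graph.bonds
                     if (b.i in core) != (b.j in core)})
    sub = _induced_subgraph(graph, keep)
    return Scaffold(graph=sub, attachment_points=tuple(attach),
                    source_smiles=graph.smiles)


def build_scaffold_pool(graphs: list[MolecularGraph]) -> list[Scaffold]:
    """Harvest one scaffold per distinct (scaffold, attachment-count)."""
    pool: list[Scaffold] = []
    seen: set[tuple[str, int]] = set()
    from .mol_io import to_smiles
    for g in graphs:
        scaf = extract_scaffold(g)
        if scaf is None or not scaf.attachment_points:
            continue
        key = (to_smiles(scaf.graph, masked_as_dummy=False),
               len(scaf.attachment_points))
        if key not in seen:
            seen.add(key)
            pool.append(scaf)
    return pool


def scaffold_hop(graph: MolecularGraph, config: RunConfig,
                 scaffold_pool: list[Scaffold],
                 rng: np.random.Generator) -> AugmentedView:
    """Swap the Murcko scaffold for a pool scaffold with the same number of
    attachment points; side chains reattach by single bonds at matched
    points.  Identity for acyclic molecules, with probability
    1 - hop_probability, or when no compatible scaffold validates."""
    do_hop = rng.random() < config.hop_probability
    own = extract_scaffold(graph) if do_hop else None
    if not do_hop or own is None:
        return _identity_view(graph, "scaffold_hop", {"hopped": False})
    core = scaffold_atoms(graph)
    n_attach = len({a for b in graph.bonds if (b.i in core) != (b.j in core)
                    for a in (b.i, b.j) if a in core})
    candidates = [s for s in scaffold_pool
                  if len(s.attachment_points) == n_attach
                  and s.source_smiles != graph.smiles]
    rng_order = rng.permutation(len(candidates))
    for ci in rng_order:
        cand = candidates[int(ci)]
        view = _attach_side_chains(graph, core, cand)
        if view is not None:
            return AugmentedView(view, "scaffold_hop",
                                 {"hopped": True,
                                  "new_scaffold": cand.source_smiles})
    logger.info("scaffold_hop: no compatible pool scaffold; identity")
    return _identity_view(graph, "scaffold_hop", {"hopped": False})


def _attach_side_chains(graph: MolecularGraph, core: set[int],
                        scaffold: Scaffold) -> MolecularGraph | None:
    """Rebuild the molecule with ``scaffold`` replacing its core.  Returns
    None when the reassembled graph violates valence."""
    side_atoms = sorted(set(range(graph.n_atoms)) - core)
    if not side_atoms:
        chains: list[set[int]] = []
    else:
        chains = connected_components(graph, set(side_atoms))
    # each chain connects to exactly one core atom through one bond
    anchors: list[tuple[set[int], int, int]] = []  # (chain, chain_atom, core_atom)
    for chain in chains:
        links = [(b.i if b.i in chain else b.j, b.j if b.i in chain else b.i)
                 for b in graph.bonds
                 if (b.i in chain) != (b.j in chain)
                 and (b.i in core or b.j in core)]
        if len(links) != 1:
            return None  # chain bridging two core sites: skip this hop
        anchors.append((chain, links[0][0], links[0][1]))
    new = scaffold.graph.copy()
    attach_order = list(scaffold.attachment_points)
    if len(anchors) > len(attach_order):
        return None
    offset_atoms = list(new.atoms)
    offset_bonds = list(new.bonds)
    mapping: dict[int, int] = {}
    for (chain, chain_atom, _), attach_at in zip(anchors, attach_order):
        base = len(offset_atoms)
        ordered = sorted(chain)
        for old in ordered:
            rec = graph.atoms[old]
            mapping[old] = base + ordered.index(old)
            offset_atoms.append(rec)
        for b in graph.bonds:
            if b.i in chain and b.j in chain:
                offset_bonds.append(BondRecord(mapping[b.i], mapping[b.j],
                                               b.order, b.in_ring))
        offset_bonds.append(BondRecord(attach_at, mapping[chain_atom], 1.0,
                                       False))
    assembled = MolecularGraph(atoms=offset_atoms, bonds=offset_bonds,
                               smiles=graph.smiles)
    # recompute degrees / shrink implicit H at junction atoms
    assembled = _refresh_records(assembled)
    try:
        validate_graph(assembled)
    except Exception:
        return None
    featurize(assembled)
    _reserialize(assembled)
    return assembled


def _refresh_records(graph: MolecularGraph) -> MolecularGraph:
    """Recompute degrees and clamp implicit H to the valence budget."""
    atoms = []
    for idx, rec in enumerate(graph.atoms):
        deg = len(graph.neighbors(idx))
        allowed = VALENCE_TABLE.get(rec.symbol)
        order_sum = graph.bond_order_sum(idx)
        if allowed is None:
            h = rec.implicit_h
        else:
            budget = max(allowed) + abs(rec.formal_charge) - order_sum
            h = int(max(0, min(rec.implicit_h, math.floor(budget + 1e-9))))
        atoms.append(AtomRecord(rec.symbol, rec.formal_charge, deg,
                                rec.aromatic, h))
    return MolecularGraph(atoms=atoms, bonds=list(graph.bonds),
                          smiles=graph.smiles)


def sample_view(graph: MolecularGraph, config: RunConfig,
                rng: np.random.Generator,
                scaffold_pool: list[Scaffold] | None = None) -> AugmentedView:
    """One augmented view, operator drawn by ensemble weight."""
    weights = np.asarray(config.ensemble_weights, dtype=np.float64)
    if weights.sum() <= 0:
        raise ValueError("ensemble weights must sum to a positive value")
    probs = weights / weights.sum()
    op = OPERATORS[int(rng.choice(len(OPERATORS), p=probs))]
    return apply_operator(op, graph, config, rng, scaffold_pool)


def make_views(graph: MolecularGraph, config: RunConfig,
               rng: np.random.Generator,
               scaffold_pool: list[Scaffold] | None = None
               ) -> tuple[AugmentedView, AugmentedView]:
    """Two independent augmented views, operator drawn by ensemble weight."""
    return (sample_view(graph, config, rng, scaffold_pool),
            sample_view(graph, config, rng, scaffold_pool))


def apply_operator(op: str, graph: MolecularGraph, config: RunConfig,
                   rng: np.random.Generator,
                   scaffold_pool: list[Scaffold] | None = None
                   ) -> AugmentedView:
    if op == "atom_mask":
        return atom_mask(graph, config, rng)
    if op == "bond_perturb":
        return bond_perturb(graph, config, rng)
    if op == "subgraph_sample":
        return subgraph_sample(graph, config, rng)
    if op == "scaffold_hop":
        return scaffold_hop(graph, config, scaffold_pool or [], rng)
    raise ValueError(f"unknown operator {op!r}; choose from {OPERATORS}")
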