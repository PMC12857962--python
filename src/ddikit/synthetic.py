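"""Synthetic benchmark generator: valence-valid molecules and rule-labeled
drug-pair datasets.

Molecules are assembled from a fragment grammar — an alkyl backbone
decorated with aromatic rings (benzene / pyridine) and functional groups
(carboxyl, amine, hydroxyl, carbonyl, sulfonyl, halogens) — every fragment
attaching through a single bond to a backbone carbon, which keeps assembly
valence-safe by construction.  Every emitted SMILES round-trips through the
package parser.

Pair labels come from a deterministic, symmetric functional-group
interaction rule (R1): drugs interact when one carries an amine and the
other a carboxyl group, or when both are aromatic and at least one carries a
halogen.  Optional label noise flips an epsilon fraction of labels.  A
pattern-matching oracle applying the rule directly achieves accuracy 1 -
epsilon on a noisy dataset — the ceiling trained models are measured
against.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import has_group
from .mol_io import (DrugTable, MolecularGraph, PairRecord, parse_smiles,
                     write_drug_table, write_pair_table)

# fragment -> (SMILES branch text, heavy-atom count)
FRAGMENTS: dict[str, tuple[str, int]] = {
    "benzene": ("c1ccccc1", 6),
    "pyridine": ("c1ccncc1", 6),
    "carboxyl": ("C(=O)O", 3),
    "amine": ("N", 1),
    "hydroxyl": ("O", 1),
    "carbonyl": ("C(C)=O", 3),
    "sulfonyl": ("S(C)(=O)=O", 4),
    "halogen_F": ("F", 1),
    "halogen_Cl": ("Cl", 1),
    "halogen_Br": ("Br", 1),
}

DEFAULT_FRAGMENT_WEIGHTS: dict[str, float] = {
    "benzene": 1.5, "pyridine": 0.7, "carboxyl": 1.2, "amine": 1.2,
    "hydroxyl": 0.8, "carbonyl": 0.6, "sulfonyl": 0.4, "halogen_F": 0.5,
    "halogen_Cl": 0.5, "halogen_Br": 0.3,
}

RULES = ("R1",)


@dataclass
class GeneratorConfig:
    n_drugs: int = 300
    min_atoms: int = 6
    max_atoms: int = 24
    fragment_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRAGMENT_WEIGHTS))
    rule: str = "R1"
    label_noise: float = 0.0
    n_pairs: int = 3000
    pos_fraction: float = 0.5
    seed: int = 0
    max_retries: int = 200

    def __post_init__(self):
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.min_atoms < 2 or self.max_atoms < self.min_atoms:
            raise ValueError("invalid atom-count range")
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; available: {RULES}")


def generate_molecule(config: GeneratorConfig,
                      rng: np.random.Generator) -> str:
    """One fragment-grammar SMILES with atom count in the configured range.

    Rejection-samples until the string parses and fits; deterministic under
    a fixed generator state.
    """
    names = sorted(config.fragment_weights)
    weights = np.asarray([config.fragment_weights[n] for n in names])
    if weights.sum() <= 0:
        raise ValueError("fragment weights must sum to a positive value")
    probs = weights / weights.sum()
    for _ in range(config.max_retries):
        chain_len = int(rng.integers(3, 9))
        n_branches = int(rng.integers(1, 5))
        # branch capacity: interior chain carbons take <= 2 branches, ends <= 3
        capacity = {i: (3 if i in (0, chain_len - 1) else 2)
                    for i in range(chain_len)}
        branches: dict[int, list[str]] = {i: [] for i in range(chain_len)}
        atom_count = chain_len
        for _ in range(n_branches):
            name = names[int(rng.choice(len(names), p=probs))]
            frag, frag_atoms = FRAGMENTS[name]
            spots = [i for i, cap in capacity.items() if cap > 0]
            if not spots or atom_count + frag_atoms > config.max_atoms:
                continue
            spot = int(rng.choice(spots))
            capacity[spot] -= 1
            branches[spot].append(frag)
            atom_count += frag_atoms
        if atom_count < config.min_atoms:
            continue
        smiles = "".join(
            "C" + "".join(f"({b})" for b in branches[i])
            for i in range(chain_len))
        try:
            graph = parse_smiles(smiles)
        except Exception:
            continue
        if config.min_atoms <= graph.n_atoms <= config.max_atoms:
            return smiles
    raise RuntimeError("molecule generation exhausted retries; "
                       "check fragment weights / atom range")


def interaction_rule(graph_a: MolecularGraph, graph_b: MolecularGraph,
                     rule: str = "R1") -> tuple[int, str]:
    """Deterministic symmetric label plus the clause that fired."""
    if rule != "R1":
        raise ValueError(f"unknown rule {rule!r}; available: {RULES}")
    amine_a, amine_b = has_group(graph_a, "amine"), has_group(graph_b, "amine")
    carb_a = has_group(graph_a, "carboxyl")
    carb_b = has_group(graph_b, "carboxyl")
    if (amine_a and carb_b) or (amine_b and carb_a):
        return 1, "amine_carboxyl"
    arom_a = has_group(graph_a, "aromatic_ring")
    arom_b = has_group(graph_b, "aromatic_ring")
    hal_a = has_group(graph_a, "halogen_on_carbon")
    hal_b = has_group(graph_b, "halogen_on_carbon")
    if arom_a and arom_b and (hal_a or hal_b):
        return 1, "aromatic_halogen"
    return 0, "none"


@dataclass
class SyntheticDataset:
    drugs: DrugTable
    pairs: list[PairRecord]
    trace: list[str]          # rule clause per pair (before noise)
    flipped: np.ndarray       # bool per pair: label flipped by noise
    config: GeneratorConfig


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Drug table + balanced labeled pairs under the interaction rule."""
    rng = np.random.default_rng(config.seed)
    drugs = DrugTable()
    seen: set[str] = set()
    idx = 0
    attempts = 0
    while len(drugs) < config.n_drugs:
        attempts += 1
        if attempts > config.max_retries * config.n_drugs:
            raise RuntimeError("could not generate enough distinct molecules")
        smiles = generate_molecule(config, rng)
        if smiles in seen:
            continue
        seen.add(smiles)
        drugs.add(f"SYN{idx:05d}", smiles)
        idx += 1
    ids = drugs.ids()
    n = len(ids)
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    rng.shuffle(all_pairs)
    want_pos = int(round(config.n_pairs * config.pos_fraction))
    want_neg = config.n_pairs - want_pos
    pos: list[tuple[int, int, str]] = []
    neg: list[tuple[int, int, str]] = []
    for i, j in all_pairs:
        if len(pos) >= want_pos and len(neg) >= want_neg:
            break
        label, clause = interaction_rule(drugs.graph(ids[i]),
                                         drugs.graph(ids[j]), config.rule)
        if label == 1 and len(pos) < want_pos:
            pos.append((i, j, clause))
        elif label == 0 and len(neg) < want_neg:
            neg.append((i, j, clause))
    if len(pos) < want_pos or len(neg) < want_neg:
        raise RuntimeError(
            f"positive/negative ratio unattainable: found {len(pos)} pos / "
            f"{len(neg)} neg, wanted {want_pos}/{want_neg}; adjust fragment "
            "weights or n_drugs")
    merged = [(i, j, clause, 1) for i, j, clause in pos] \
        + [(i, j, clause, 0) for i, j, clause in neg]
    order = rng.permutation(len(merged))
    merged = [merged[k] for k in order]
    flipped = np.zeros(len(merged), dtype=bool)
    if config.label_noise > 0:
        n_flip = int(round(config.label_noise * len(merged)))
        flip_idx = rng.choice(len(merged), size=n_flip, replace=False)
        flipped[flip_idx] = True
    pairs, trace = [], []
    for k, (i, j, clause, label) in enumerate(merged):
        y = label ^ int(flipped[k])
        pairs.append(PairRecord(ids[i], ids[j], label=y))
        trace.append(clause)
    return SyntheticDataset(drugs=drugs, pairs=pairs, trace=trace,
                            flipped=flipped, config=config)


def rule_oracle_accuracy(dataset: SyntheticDataset,
                         subset: list[int] | None = None) -> float:
    """Accuracy of the pattern-matching oracle that applies the rule
    directly (the learnability ceiling: 1 - label_noise in expectation)."""
    idx = range(len(dataset.pairs)) if subset is None else subset
    correct = 0
    total = 0
    for k in idx:
        r = dataset.pairs[k]
        label, _ = interaction_rule(dataset.drugs.graph(r.drug_a),
                                    dataset.drugs.graph(r.drug_b),
                                    dataset.config.rule)
        correct += int(label == r.label)
        total += 1
    return correct / max(total, 1)


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict:
    """Write drug table, pair table, rule trace, and a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_drug_table(dataset.drugs, out / "drugs.tsv")
    write_pair_table(dataset.pairs, out / "pairs.tsv")
    pd.DataFrame({
        "drug_a": [r.drug_a for r in dataset.pairs],
        "drug_b": [r.drug_b for r in dataset.pairs],
        "label": [r.label for r in dataset.pairs],
        "rule_clause": dataset.trace,
        "noise_flipped": dataset.flipped.astype(int),
    }).to_csv(out / "rule_trace.tsv", sep="\t", index=False)
    manifest = {
        "config": {k: (v if not isinstance(v, dict) else dict(v))
                   for k, v in asdict(dataset.config).items()},
        "n_drugs": len(dataset.drugs),
        "n_pairs": len(dataset.pairs),
        "n_positive": sum(r.label for r in dataset.pairs),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
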