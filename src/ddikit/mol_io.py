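"""Molecular graph construction from SMILES and tabular drug/pair I/O.

A drug is a molecular graph G = (V, E, Xv, Xe): atoms with per-atom feature
rows, bonds with per-bond feature rows, and a binary symmetric adjacency.
Hydrogens are implicit (heavy-atom graphs); atom indices follow SMILES
reading order, 0-based.

SMILES parsing is delegated to RDKit behind the :func:`parse_smiles`
interface; an alternative backend can be registered via
:func:`set_parser_backend`.  The valence table used by the augmentation
validity checks is the package's own and is independent of RDKit's
sanitization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

try:  # RDKit emits noisy C++ logs; keep them off by default
    from rdkit import Chem, RDLogger
    RDLogger.DisableLog("rdApp.*")
except ImportError as _e:  # pragma: no cover - rdkit is a hard dependency
    raise ImportError("ddikit.mol_io requires rdkit") from _e


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class ChemistryError(ValueError):
    """Raised when a structure violates chemical (valence) constraints."""


# Maximum bonding capacity per element; aromatic bonds count 1.5.
VALENCE_TABLE: dict[str, tuple[int, ...]] = {
    "C": (4,), "N": (3,), "O": (2,), "S": (2, 4, 6), "P": (3, 5),
    "F": (1,), "Cl": (1,), "Br": (1,), "I": (1,), "B": (3,),
}

ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")  # + "other" slot

BOND_ORDERS = (1.0, 2.0, 3.0, 1.5)  # single, double, triple, aromatic


@dataclass(frozen=True)
class AtomRecord:
    symbol: str
    formal_charge: int
    degree: int
    aromatic: bool
    implicit_h: int


@dataclass(frozen=True)
class BondRecord:
    i: int
    j: int
    order: float  # 1, 2, 3 or 1.5 (aromatic)
    in_ring: bool


@dataclass
class MolecularGraph:
    atoms: list[AtomRecord]
    bonds: list[BondRecord]
    smiles: str
    atom_features: np.ndarray | None = None  # (n, d_atom)
    bond_features: np.ndarray | None = None  # (m, d_bond)
    mask_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def __post_init__(self):
        if self.mask_flags.size == 0:
            self.mask_flags = np.zeros(self.n_atoms, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def adjacency(self) -> np.ndarray:
        n = self.n_atoms
        A = np.zeros((n, n), dtype=np.float64)
        for b in self.bonds:
            A[b.i, b.j] = A[b.j, b.i] = 1.0
        return A

    def bond_order_sum(self, atom: int) -> float:
        return sum(b.order for b in self.bonds if atom in (b.i, b.j))

    def neighbors(self, atom: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == atom:
                out.append(b.j)
            elif b.j == atom:
                out.append(b.i)
        return out

    def copy(self) -> "MolecularGraph":
        return MolecularGraph(
            atoms=list(self.atoms), bonds=list(self.bonds), smiles=self.smiles,
            atom_features=None if self.atom_features is None else self.atom_features.copy(),
            bond_features=None if self.bond_features is None else self.bond_features.copy(),
            mask_flags=self.mask_flags.copy(),
        )


def check_valence(graph: MolecularGraph, atom: int,
                  extra_order: float = 0.0) -> bool:
    """Whether ``atom`` (with optional extra bond order) fits the valence table.

    Implicit hydrogens shrink to absorb added bond order, so the check is
    bond-order-sum ≤ max allowed valence for the element (charges relax the
    bound by |charge|).
    """
    rec = graph.atoms[atom]
    allowed = VALENCE_TABLE.get(rec.symbol)
    if allowed is None:
        return True  # unknown element: no constraint enforced
    total = graph.bond_order_sum(atom) + extra_order
    return total <= max(allowed) + abs(rec.formal_charge)


def validate_graph(graph: MolecularGraph) -> None:
    """Raise ChemistryError / ValueError on any structural invariant breach."""
    n = graph.n_atoms
    for b in graph.bonds:
        if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
            raise ValueError(f"bond ({b.i},{b.j}) has invalid endpoints for n={n}")
        if b.order not in BOND_ORDERS:
            raise ValueError(f"bond ({b.i},{b.j}) has unsupported order {b.order}")
    seen = set()
    for b in graph.bonds:
        key = (min(b.i, b.j), max(b.i, b.j))
        if key in seen:
            raise ValueError(f"duplicate bond {key}")
        seen.add(key)
    for idx, rec in enumerate(graph.atoms):
        allowed = VALENCE_TABLE.get(rec.symbol)
        if allowed is None:
            continue
        total = graph.bond_order_sum(idx) + rec.implicit_h
        if total > max(allowed) + abs(rec.formal_charge) + 1e-9:
            raise ChemistryError(
                f"atom {idx} ({rec.symbol}): bond order sum + implicit H = "
                f"{total} exceeds max valence {max(allowed)}")
    if graph.atom_features is not None and graph.atom_features.shape[0] != n:
        raise ValueError("atom_features row count != n_atoms")
    if graph.bond_features is not None and graph.bond_features.shape[0] != graph.n_bonds:
        raise ValueError("bond_features row count != n_bonds")


# ---------------------------------------------------------------------------
# SMILES parsing (RDKit backend, pluggable)
# ---------------------------------------------------------------------------

def _rdkit_bond_order(bond) -> float:
    bt = bond.GetBondType()
    if bt == Chem.BondType.AROMATIC:
        return 1.5
    if bt == Chem.BondType.SINGLE:
        return 1.0
    if bt == Chem.BondType.DOUBLE:
        return 2.0
    if bt == Chem.BondType.TRIPLE:
        return 3.0
    raise ChemistryError(f"unsupported bond type {bt}")


def _parse_smiles_rdkit(smiles: str) -> MolecularGraph:
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SmilesParseError(f"malformed SMILES {smiles!r} (syntax error)")
    try:
        Chem.SanitizeMol(mol)
    except Chem.AtomValenceException as e:
        raise ChemistryError(f"valence violation in {smiles!r}: {e}") from e
    except Exception as e:
        raise SmilesParseError(f"cannot sanitize {smiles!r}: {e}") from e
    atoms = [
        AtomRecord(
            symbol=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            degree=a.GetDegree(),
            aromatic=a.GetIsAromatic(),
            implicit_h=a.GetTotalNumHs(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [
        BondRecord(
            i=b.GetBeginAtomIdx(), j=b.GetEndAtomIdx(),
            order=_rdkit_bond_order(b), in_ring=b.IsInRing(),
        )
        for b in mol.GetBonds()
    ]
    return MolecularGraph(atoms=atoms, bonds=bonds, smiles=smiles)


_parser_backend = _parse_smiles_rdkit


def set_parser_backend(fn) -> None:
    """Replace the SMILES parsing backend (same signature as parse_smiles)."""
    global _parser_backend
    _parser_backend = fn


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a validated :class:`MolecularGraph`.

    Atom order follows SMILES reading order; hydrogens are implicit.
    Raises :class:`SmilesParseError` on syntax errors and
    :class:`ChemistryError` on valence violations.
    """
    graph = _parser_backend(smiles)
    validate_graph(graph)
    return graph


def to_rdkit(graph: MolecularGraph, masked_as_dummy: bool = False):
    """Rebuild an RDKit Mol from a graph (used for scaffolds & serialization).

    Masked atoms become dummy (*) atoms when ``masked_as_dummy``.
    """
    rw = Chem.RWMol()
    for idx, rec in enumerate(graph.atoms):
        if masked_as_dummy and graph.mask_flags[idx]:
            atom = Chem.Atom(0)
        else:
            atom = Chem.Atom(rec.symbol)
            atom.SetFormalCharge(rec.formal_charge)
            atom.SetIsAromatic(rec.aromatic)
        rw.AddAtom(atom)
    order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                 3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
    for b in graph.bonds:
        rw.AddBond(b.i, b.j, order_map[b.order])
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        # augmented views may not round-trip through full aromaticity
        # perception; fall back to a partial sanitize
        mol.UpdatePropertyCache(strict=False)
    return mol


def to_smiles(graph: MolecularGraph, masked_as_dummy: bool = True) -> str:
    """Serialize a graph back to canonical SMILES (masked atoms as ``*``)."""
    return Chem.MolToSmiles(to_rdkit(graph, masked_as_dummy=masked_as_dummy))


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSchema:
    """Versioned one-hot descriptor schema for atoms and bonds.

    Atom rows: element one-hot over ELEMENTS + "other" (10) | degree one-hot
    0-5 (6) | formal charge one-hot -2..+2 (5) | aromatic flag (1) |
    implicit-H one-hot 0-4 (5).  Bond rows: order one-hot
    {single, double, triple, aromatic} (4) | in-ring flag (1).
    """
    version: str = "v1"

    @property
    def d_atom(self) -> int:
        return len(ELEMENTS) + 1 + 6 + 5 + 1 + 5

    @property
    def d_bond(self) -> int:
        return 5

    def atom_row(self, rec: AtomRecord) -> np.ndarray:
        row = np.zeros(self.d_atom)
        try:
            row[ELEMENTS.index(rec.symbol)] = 1.0
        except ValueError:
            row[len(ELEMENTS)] = 1.0  # reserved "other" slot
            logger.info("element %s outside schema vocabulary -> 'other'",
                        rec.symbol)
        off = len(ELEMENTS) + 1
        row[off + min(rec.degree, 5)] = 1.0
        off += 6
        row[off + int(np.clip(rec.formal_charge, -2, 2)) + 2] = 1.0
        off += 5
        row[off] = 1.0 if rec.aromatic else 0.0
        off += 1
        row[off + min(rec.implicit_h, 4)] = 1.0
        return row

    def bond_row(self, rec: BondRecord) -> np.ndarray:
        row = np.zeros(self.d_bond)
        row[BOND_ORDERS.index(rec.order)] = 1.0
        row[4] = 1.0 if rec.in_ring else 0.0
        return row


DEFAULT_SCHEMA = FeatureSchema()


def featurize(graph: MolecularGraph,
              schema: FeatureSchema = DEFAULT_SCHEMA) -> MolecularGraph:
    """Populate Xv and Xe in place (and return the graph).  Deterministic for
    a fixed schema version."""
    graph.atom_features = (
        np.stack([schema.atom_row(a) for a in graph.atoms])
        if graph.atoms else np.zeros((0, schema.d_atom)))
    graph.bond_features = (
        np.stack([schema.bond_row(b) for b in graph.bonds])
        if graph.bonds else np.zeros((0, schema.d_bond)))
    return graph


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

@dataclass
class PairRecord:
    drug_a: str
    drug_b: str
    label: int | None = None
    prediction: float | None = None


class DrugTable:
    """Ordered map drug_id -> (smiles, MolecularGraph)."""

    def __init__(self, entries: dict[str, str] | None = None,
                 schema: FeatureSchema = DEFAULT_SCHEMA):
        self._schema = schema
        self._entries: dict[str, tuple[str, MolecularGraph]] = {}
        if entries:
            for drug_id, smiles in entries.items():
                self.add(drug_id, smiles)

    def add(self, drug_id: str, smiles: str) -> MolecularGraph:
        if drug_id in self._entries:
            raise ValueError(f"duplicate drug id {drug_id!r}")
        graph = featurize(parse_smiles(smiles), self._schema)
        self._entries[drug_id] = (smiles, graph)
        return graph

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self._entries

    def ids(self) -> list[str]:
        return list(self._entries)

    def smiles(self, drug_id: str) -> str:
        return self._entries[drug_id][0]

    def graph(self, drug_id: str) -> MolecularGraph:
        return self._entries[drug_id][1]

    def items(self):
        return ((k, v[0], v[1]) for k, v in self._entries.items())


def read_drug_table(path, schema: FeatureSchema = DEFAULT_SCHEMA) -> DrugTable:
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"drug_id", "smiles"}
    if not required <= set(df.columns):
        raise ValueError(f"drug table needs columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    return DrugTable(dict(zip(df["drug_id"].astype(str), df["smiles"])),
                     schema=schema)


def write_drug_table(table: DrugTable, path) -> None:
    pd.DataFrame(
        [(i, s) for i, s, _ in table.items()], columns=["drug_id", "smiles"]
    ).to_csv(path, sep="\t", index=False)


def read_pair_table(path, drugs: DrugTable | None = None) -> list[PairRecord]:
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"drug_a", "drug_b"} <= set(df.columns):
        raise ValueError(f"pair table needs drug_a/drug_b columns, got "
                         f"{list(df.columns)}")
    records = []
    for row in df.itertuples(index=False):
        label = int(row.label) if hasattr(row, "label") and pd.notna(row.label) else None
        pred = (float(row.probability)
                if hasattr(row, "probability") and pd.notna(row.probability) else None)
        records.append(PairRecord(str(row.drug_a), str(row.drug_b),
                                  label=label, prediction=pred))
    if drugs is not None:
        missing = sorted({d for r in records for d in (r.drug_a, r.drug_b)
                          if d not in drugs})
        if missing:
            raise KeyError(f"pair table references unknown drug ids: {missing}")
    return records


def write_pair_table(records: list[PairRecord], path) -> None:
    pd.DataFrame(
        [(r.drug_a, r.drug_b, r.label) for r in records],
        columns=["drug_a", "drug_b", "label"],
    ).to_csv(path, sep="\t", index=False)


def write_predictions(records: list[PairRecord], path) -> None:
    """Write drug_a / drug_b / probability TSV (6-decimal probabilities)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_a\tdrug_b\tprobability\n")
        for r in records:
            fh.write(f"{r.drug_a}\t{r.drug_b}\t{r.prediction:.6f}\n")
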