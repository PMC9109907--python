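"""Molecular graphs, atom/bond featurization, circular fingerprints, scaffolds.

A compound is represented as an undirected graph ``g = (V, E, X, E_feat)``:
atoms are nodes, covalent bonds are edges, ``X`` holds one feature vector per
atom and ``E_feat`` one per bond.  Atom features are the concatenation, in
fixed order, of six blocks::

    valence       one-hot, 7 slots (0..6, last slot also catches >6)
    number of Hs  one-hot, 6 slots (0..5, last slot also catches >5)
    hybridization one-hot, 5 slots (sp, sp2, sp3, sp3d, other)
    symbol        one-hot, 11 slots (C N O S F Cl Br I P B + other)
    degree        one-hot, 7 slots (0..6, last slot also catches >6)
    aromatic      single 0/1 flag

for a total dimension of 37.  Bond features are a 4-slot bond-type one-hot
(single, double, triple, aromatic) plus conjugation and ring-membership
flags (dimension 6).  Hydrogens are implicit: they are counted in the
"number of Hs" block but are not graph nodes, and degree is the heavy-atom
degree.  Multi-fragment inputs (salts) are reduced to the largest fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "FeatureConfig",
    "MolecularGraph",
    "Fingerprint",
    "parse_smiles",
    "compute_fingerprint",
    "extract_scaffold",
    "read_smiles_file",
    "read_smiles_csv",
]

_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
)

_BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)


@dataclass(frozen=True)
class FeatureConfig:
    """Vocabularies for the one-hot atom feature blocks.

    The symbol vocabulary covers the ten elements that dominate screening
    libraries; anything else (and any attribute above the top of its block)
    lands in the block's final catch-all slot, so featurization is total.
    """

    symbols: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B")
    max_valence: int = 6
    max_num_h: int = 5
    max_degree: int = 6
    n_hybridization: int = 5  # sp, sp2, sp3, sp3d, other

    @property
    def atom_dim(self) -> int:
        return (
            (self.max_valence + 1)
            + (self.max_num_h + 1)
            + self.n_hybridization
            + (len(self.symbols) + 1)
            + (self.max_degree + 1)
            + 1
        )

    @property
    def bond_dim(self) -> int:
        return len(_BOND_TYPES) + 2  # type one-hot + conjugated + in-ring


DEFAULT_FEATURES = FeatureConfig()


@dataclass(frozen=True)
class MolecularGraph:
    """One compound as an undirected featurized graph.

    ``bonds`` stores each bond once as an ``(i, j)`` pair with ``i < j``;
    ``E`` is aligned row-for-row with ``bonds``.
    """

    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int], ...]
    X: np.ndarray
    E: np.ndarray
    source_smiles: str
    canonical_smiles: str

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def is_empty(self) -> bool:
        return self.n_atoms == 0

    def neighbors(self, i: int) -> tuple[int, ...]:
        """N(i): indices of atoms sharing a bond with atom ``i``."""
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return tuple(sorted(out))

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.canonical_smiles) if self.canonical_smiles else Chem.Mol()
        if mol is None:  # pragma: no cover - canonical SMILES always reparses
            raise ValueError(f"internal: canonical SMILES failed to reparse: {self.canonical_smiles!r}")
        return mol


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary circular (Morgan/ECFP-style) fingerprint."""

    bits: np.ndarray
    radius: int
    length: int

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1 or bits.size != self.length:
            raise ValueError(f"fingerprint bits must be a length-{self.length} vector")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")
        object.__setattr__(self, "bits", bits)

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())


def _one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size, dtype=np.float32)
    v[index] = 1.0
    return v


def _capped(value: int, cap: int) -> int:
    # out-of-vocabulary values share the top slot rather than crashing
    return min(value, cap)


def _atom_features(atom: Chem.Atom, cfg: FeatureConfig) -> np.ndarray:
    valence = _one_hot(_capped(atom.GetTotalValence(), cfg.max_valence), cfg.max_valence + 1)
    num_h = _one_hot(_capped(atom.GetTotalNumHs(), cfg.max_num_h), cfg.max_num_h + 1)
    try:
        hyb_idx = _HYBRIDIZATIONS.index(atom.GetHybridization())
    except ValueError:
        hyb_idx = cfg.n_hybridization - 1
    hyb = _one_hot(hyb_idx, cfg.n_hybridization)
    try:
        sym_idx = cfg.symbols.index(atom.GetSymbol())
    except ValueError:
        sym_idx = len(cfg.symbols)
    sym = _one_hot(sym_idx, len(cfg.symbols) + 1)
    degree = _one_hot(_capped(atom.GetDegree(), cfg.max_degree), cfg.max_degree + 1)
    aromatic = np.array([float(atom.GetIsAromatic())], dtype=np.float32)
    return np.concatenate([valence, num_h, hyb, sym, degree, aromatic])


def _bond_features(bond: Chem.Bond, cfg: FeatureConfig) -> np.ndarray:
    try:
        type_idx = _BOND_TYPES.index(bond.GetBondType())
    except ValueError:
        type_idx = 0  # exotic bond orders are treated as single bonds
    type_oh = _one_hot(type_idx, len(_BOND_TYPES))
    flags = np.array([float(bond.GetIsConjugated()), float(bond.IsInRing())], dtype=np.float32)
    return np.concatenate([type_oh, flags])


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    return max(frags, key=lambda f: f.GetNumAtoms())


def _graph_from_mol(mol: Chem.Mol, source: str, cfg: FeatureConfig) -> MolecularGraph:
    if mol.GetNumAtoms() == 0:
        return MolecularGraph(
            atoms=(),
            bonds=(),
            X=np.zeros((0, cfg.atom_dim), dtype=np.float32),
            E=np.zeros((0, cfg.bond_dim), dtype=np.float32),
            source_smiles=source,
            canonical_smiles="",
        )
    # renumber to canonical atom ranks so different SMILES spellings of the
    # same molecule yield the same graph, atom for atom
    ranks = list(Chem.CanonicalRankAtoms(mol))
    order = sorted(range(len(ranks)), key=ranks.__getitem__)
    mol = Chem.RenumberAtoms(mol, order)
    atoms = tuple(a.GetSymbol() for a in mol.GetAtoms())
    X = np.stack([_atom_features(a, cfg) for a in mol.GetAtoms()])
    bonds, efeat = [], []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append((min(i, j), max(i, j)))
        efeat.append(_bond_features(b, cfg))
    key = np.argsort([i * mol.GetNumAtoms() + j for i, j in bonds]) if bonds else []
    bonds = tuple(bonds[k] for k in key)
    E = (
        np.stack([efeat[k] for k in key])
        if bonds
        else np.zeros((0, cfg.bond_dim), dtype=np.float32)
    )
    return MolecularGraph(
        atoms=atoms,
        bonds=bonds,
        X=X.astype(np.float32),
        E=E.astype(np.float32),
        source_smiles=source,
        canonical_smiles=Chem.MolToSmiles(mol),
    )


def parse_smiles(smiles: str, feature_config: FeatureConfig | None = None) -> MolecularGraph:
    """Parse a SMILES string into a featurized :class:`MolecularGraph`.

    Salts / multi-fragment inputs keep the largest fragment.  Raises
    ``ValueError`` naming the input when RDKit cannot parse it.
    """
    cfg = feature_config or DEFAULT_FEATURES
    if not smiles or not smiles.strip():
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES: {smiles!r}")
    mol = _largest_fragment(mol)
    return _graph_from_mol(mol, smiles, cfg)


def compute_fingerprint(
    graph: MolecularGraph, radius: int = 3, length: int = 1024
) -> Fingerprint:
    """Circular (Morgan) fingerprint of a molecular graph.

    Deterministic for a fixed molecule and configuration, and independent of
    the atom ordering of the originating SMILES.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if length < 1:
        raise ValueError("length must be >= 1")
    if graph.is_empty:
        return Fingerprint(np.zeros(length, dtype=np.uint8), radius, length)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=length)
    fp = gen.GetFingerprint(graph.to_mol())
    return Fingerprint(np.array(fp, dtype=np.uint8), radius, length)


def extract_scaffold(
    graph: MolecularGraph, feature_config: FeatureConfig | None = None
) -> MolecularGraph:
    """Bemis-Murcko scaffold (ring systems plus linkers) of a molecule.

    Acyclic molecules map to the empty-scaffold sentinel, a graph with zero
    atoms (``is_empty`` is true).  Idempotent: the scaffold of a scaffold is
    itself.
    """
    cfg = feature_config or DEFAULT_FEATURES
    if graph.is_empty:
        return graph
    scaffold = MurckoScaffold.GetScaffoldForMol(graph.to_mol())
    return _graph_from_mol(scaffold, graph.source_smiles, cfg)


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a .smi file: one SMILES per line, optional whitespace-separated id.

    Returns ``(compound_id, smiles)`` pairs; lines without an id get a
    1-based positional id.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"mol{lineno}"
            out.append((cid, smiles))
    return out


def read_smiles_csv(path, smiles_column: str = "smiles", id_column: str | None = None):
    """Read (id, smiles) pairs from a CSV with a configurable SMILES column."""
    import pandas as pd

    import io

    with open(path) as fh:  # '#' is SMILES syntax; only full comment lines skipped
        text = "".join(line for line in fh if not line.startswith("#"))
    df = pd.read_csv(io.StringIO(text))
    if smiles_column not in df.columns:
        raise ValueError(f"CSV has no column {smiles_column!r}")
    if id_column is None:
        for cand in ("compound_id", "id", "name"):
            if cand in df.columns:
                id_column = cand
                break
    ids = (
        df[id_column].astype(str).tolist()
        if id_column
        else [f"mol{i + 1}" for i in range(len(df))]
    )
    return list(zip(ids, df[smiles_column].astype(str).tolist()))


def fingerprints_to_csv(
    path, ids: Sequence[str], fingerprints: Iterable[Fingerprint]
) -> None:
    """Export fingerprints as ``compound_id,bitstring`` rows."""
    with open(path, "w") as fh:
        fh.write("compound_id,bits\n")
        for cid, fp in zip(ids, fingerprints):
            fh.write(f"{cid},{''.join(map(str, fp.bits.tolist()))}\n")
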