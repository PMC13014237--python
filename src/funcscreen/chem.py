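"""Chemistry core: SMILES -> attributed directed graphs, fingerprints, scaffolds.

Molecules are represented as 2D attributed graphs with every bond stored twice
(once per direction), the form consumed by the directed message-passing
encoder. RDKit does the parsing, canonicalisation, Morgan fingerprinting and
Bemis-Murcko scaffold extraction; this module fixes the feature schema and the
conventions (largest-fragment salt stripping, implicit hydrogens,
stereochemistry ignored by features).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

# Atom feature schema: element one-hot (+ catch-all), degree one-hot,
# formal charge, aromaticity flag, attached-H one-hot. Stereochemistry is
# deliberately absent: the model is a 2D graph model.
ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
_MAX_DEGREE = 5
_MAX_NUM_H = 4

N_ATOM_FEATURES = len(ELEMENTS) + 1 + (_MAX_DEGREE + 1) + 1 + 1 + (_MAX_NUM_H + 1)
# bond order one-hot (single, double, triple, aromatic) + conjugation + ring
N_BOND_FEATURES = 4 + 1 + 1

_BOND_ORDER_INDEX = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the offending id."""

    def __init__(self, mol_id: str, smiles: str):
        self.mol_id = mol_id
        self.smiles = smiles
        super().__init__(f"unparseable SMILES for {mol_id!r}: {smiles!r}")


@dataclass(frozen=True)
class MolGraph:
    """Attributed directed molecular graph.

    ``atoms`` is an ``(n_atoms, N_ATOM_FEATURES)`` float array; ``bonds`` an
    ``(n_directed_bonds, N_BOND_FEATURES)`` float array. ``bond_src`` /
    ``bond_dst`` give, per directed bond, the source and target atom index;
    ``rev_index[i]`` is the index of the opposite direction of bond ``i``.
    """

    mol_id: str
    smiles: str  # canonical
    atoms: np.ndarray
    bonds: np.ndarray
    bond_src: np.ndarray
    bond_dst: np.ndarray
    rev_index: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_directed_bonds(self) -> int:
        return self.bonds.shape[0]


@dataclass(frozen=True)
class Fingerprint:
    """Hashed circular-substructure (Morgan / ECFP-like) binary fingerprint."""

    bits: np.ndarray  # bool vector
    radius: int
    mol_id: str

    def __len__(self) -> int:
        return self.bits.shape[0]


@dataclass(frozen=True)
class Scaffold:
    """Bemis-Murcko framework; empty string for acyclic molecules."""

    scaffold_smiles: str


def _one_hot(index: int, size: int) -> list[float]:
    v = [0.0] * size
    v[index] = 1.0
    return v


def _atom_features(atom: Chem.Atom) -> list[float]:
    symbol = atom.GetSymbol()
    elem = _one_hot(ELEMENTS.index(symbol) if symbol in ELEMENTS else len(ELEMENTS),
                    len(ELEMENTS) + 1)
    degree = _one_hot(min(atom.GetDegree(), _MAX_DEGREE), _MAX_DEGREE + 1)
    num_h = _one_hot(min(atom.GetTotalNumHs(), _MAX_NUM_H), _MAX_NUM_H + 1)
    return elem + degree + [float(atom.GetFormalCharge()),
                            1.0 if atom.GetIsAromatic() else 0.0] + num_h


def _bond_features(bond: Chem.Bond) -> list[float]:
    order = _one_hot(_BOND_ORDER_INDEX.get(bond.GetBondType(), 0), 4)
    return order + [1.0 if bond.GetIsConjugated() else 0.0,
                    1.0 if bond.IsInRing() else 0.0]


def _mol_from_smiles(smiles: str, mol_id: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(mol_id, smiles)
    # salts / mixtures: keep the largest covalent fragment
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return mol


def parse_smiles(smiles: str, mol_id: str = "") -> MolGraph:
    """Parse a SMILES string into an attributed directed graph.

    Hydrogens stay implicit; for salts/mixtures only the largest covalent
    fragment is kept. Raises :class:`SmilesParseError` on invalid input.
    """
    if not smiles:
        raise SmilesParseError(mol_id, smiles)
    mol = _mol_from_smiles(smiles, mol_id)
    canonical = Chem.MolToSmiles(mol)

    atoms = np.array([_atom_features(a) for a in mol.GetAtoms()],
                     dtype=np.float64).reshape(mol.GetNumAtoms(), N_ATOM_FEATURES)

    src, dst, feats = [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bf = _bond_features(bond)
        src += [u, v]
        dst += [v, u]
        feats += [bf, bf]
    n_db = len(src)
    rev = np.arange(n_db, dtype=np.int64)
    rev[0::2] += 1
    rev[1::2] -= 1
    return MolGraph(
        mol_id=mol_id,
        smiles=canonical,
        atoms=atoms,
        bonds=np.array(feats, dtype=np.float64).reshape(n_db, N_BOND_FEATURES),
        bond_src=np.array(src, dtype=np.int64),
        bond_dst=np.array(dst, dtype=np.int64),
        rev_index=rev,
    )


def morgan_fingerprint(graph: MolGraph | str, radius: int = 2,
                       n_bits: int = 2048) -> Fingerprint:
    """Morgan fingerprint of a molecule (defaults: radius 2, 2048 bits = ECFP4).

    Computed from the canonical SMILES, so it is invariant to the atom
    ordering of the input spelling.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 64:
        raise ValueError("n_bits must be >= 64")
    if isinstance(graph, str):
        graph = parse_smiles(graph, graph)
    mol = Chem.MolFromSmiles(graph.smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=bool)
    bits[list(bv.GetOnBits())] = True
    return Fingerprint(bits=bits, radius=radius, mol_id=graph.mol_id)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two equal-length fingerprints.

    Convention for degenerate inputs: two all-zero fingerprints are maximally
    similar (1.0); an all-zero against a non-zero one scores 0.0.
    """
    if len(a) != len(b):
        raise ValueError(f"fingerprint length mismatch: {len(a)} vs {len(b)}")
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a.bits & b.bits)) / union


def murcko_scaffold(graph: MolGraph | str) -> Scaffold:
    """Bemis-Murcko framework: ring systems plus linkers, side chains removed.

    Acyclic molecules map to the empty scaffold.
    """
    if isinstance(graph, str):
        graph = parse_smiles(graph, graph)
    smi = MurckoScaffold.MurckoScaffoldSmiles(smiles=graph.smiles)
    return Scaffold(scaffold_smiles=smi)


def read_compound_table(path: str | Path,
                        on_error: str = "skip") -> list[MolGraph]:
    """Read a compound table (CSV/TSV, header ``mol_id,smiles``, '#' comments).

    ``on_error="skip"`` logs and drops unparseable rows (bulk-curation mode);
    ``on_error="raise"`` aborts on the first bad SMILES.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)
    if not {"mol_id", "smiles"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns mol_id,smiles; got {list(df.columns)}")
    out: list[MolGraph] = []
    for row in df.itertuples(index=False):
        try:
            out.append(parse_smiles(str(row.smiles), str(row.mol_id)))
        except SmilesParseError as exc:
            if on_error == "raise":
                raise
            logger.warning("skipping unparseable compound: %s", exc)
    return out


def random_smiles_spellings(smiles: str, n: int, seed: int = 0) -> list[str]:
    """``n`` random atom-order respellings of one molecule (seeded)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, smiles)
    return list(Chem.MolToRandomSmilesVect(mol, n, randomSeed=seed))
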