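"""Planted-rule synthetic world: proteins, molecules, affinities.

Stands in for large curated bioactivity collections so the full pipeline
(curation, training, decoy ablation, zero-shot transfer, evaluation) can be
exercised offline at desk scale. The world plants a recoverable binding rule:

* each of ``n_archetypes`` latent function archetypes owns a disjoint block of
  the function-score vector (so a linear projection can recover it) and a
  preferred subset of a fixed ~20-fragment SMILES library;
* each protein draws an archetype; its function vector is the archetype
  prototype plus clipped Gaussian noise and its synthetic sequence is the
  archetype core sequence with seeded point substitutions (within-archetype
  identity is therefore higher than between-archetype identity);
* each molecule is a chain of 2-4 library fragments; it truly binds a protein
  when at least half of its fragments come from the archetype's preferred set;
* binding pairs get affinities log-uniform in [0.1, 10] uM and non-binding
  pairs in [100, 1000] uM, deliberately straddling and avoiding the 50 uM
  labeling cutoff; a ``label_flip_rate`` fraction of measured records is
  flipped (affinity resampled from the opposite range) to emulate assay noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import MolGraph, parse_smiles
from .curation import ActivityRecord, write_activity_csv
from .profunc import ProteinFunctionVector, write_function_vectors

logger = logging.getLogger(__name__)

# chainable fragments: first and last atoms are carbons able to accept one
# extra single bond, so plain concatenation always yields valid SMILES
FRAGMENT_LIBRARY: tuple[str, ...] = (
    "CC", "CCC", "CCO", "CNC", "CCN", "COC", "CC(C)C", "CC(=O)C", "CC(=O)NC",
    "CSC", "c1ccccc1", "c1ccncc1", "c1ccsc1", "c1ccoc1", "C1CCCCC1",
    "C1CCNCC1", "C1CCOCC1", "CC=CC", "CC#CC", "c1ccc2ccccc2c1",
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_METRICS = ("KI", "IC50", "EC50", "KD")
_UNITS = (("uM", 1.0), ("nM", 1e-3), ("mM", 1e3))  # unit, uM-per-unit


@dataclass(frozen=True)
class WorldSpec:
    n_archetypes: int = 4
    n_proteins: int = 50
    n_molecules: int = 400
    n_func: int = 16
    noise_sd: float = 0.1
    label_flip_rate: float = 0.05
    seed: int = 0
    # fixed world conventions (chosen once; see docs/methods.md)
    preferred_fragments: int = 6
    fragments_per_molecule: tuple[int, int] = (2, 4)
    records_per_protein: int = 80
    positive_record_fraction: float | None = None  # None = unbiased sampling
    active_affinity_um: tuple[float, float] = (0.1, 10.0)
    inactive_affinity_um: tuple[float, float] = (100.0, 1000.0)
    sequence_length: int = 80
    substitution_rate: float = 0.08

    def __post_init__(self):
        for name in ("n_archetypes", "n_proteins", "n_molecules", "n_func"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("label_flip_rate", "substitution_rate"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_func < self.n_archetypes:
            raise ValueError("n_func must allow one support slot per archetype")
        if self.preferred_fragments > len(FRAGMENT_LIBRARY):
            raise ValueError("preferred_fragments exceeds the fragment library")


@dataclass
class SyntheticWorld:
    spec: WorldSpec
    proteins: list[ProteinFunctionVector]
    molecules: list[MolGraph]
    protein_archetype: dict[str, int]
    molecule_fragments: dict[str, tuple[int, ...]]
    archetype_preferred: list[frozenset[int]]
    records: list[ActivityRecord]
    true_binding: np.ndarray  # (n_proteins, n_molecules) bool, row/col order
    flipped_pairs: set[tuple[str, str]]

    @property
    def protein_index(self) -> dict[str, int]:
        return {p.protein_id: i for i, p in enumerate(self.proteins)}

    @property
    def molecule_index(self) -> dict[str, int]:
        return {m.mol_id: i for i, m in enumerate(self.molecules)}

    def true_label(self, protein_id: str, mol_id: str) -> int:
        """Ground-truth binding (pre-flip), for evaluation."""
        return int(self.true_binding[self.protein_index[protein_id],
                                     self.molecule_index[mol_id]])


def _compatibility(fragments: Sequence[int], preferred: frozenset[int]) -> float:
    hits = sum(1 for f in fragments if f in preferred)
    return hits / len(fragments)


def binds(fragments: Sequence[int], preferred: frozenset[int]) -> bool:
    """Planted rule: binds iff >= half the fragment slots are preferred."""
    return _compatibility(fragments, preferred) >= 0.5


def _sample_affinity(rng: np.random.Generator, rng_um: tuple[float, float]) -> float:
    lo, hi = np.log10(rng_um[0]), np.log10(rng_um[1])
    return float(10.0 ** rng.uniform(lo, hi))


def generate_world(spec: WorldSpec = WorldSpec()) -> SyntheticWorld:
    """Generate a reproducible synthetic world from ``spec`` (seeded)."""
    rng = np.random.default_rng(spec.seed)
    block = spec.n_func // spec.n_archetypes
    if block < 1:
        raise ValueError("n_func too small for the archetype count")

    # archetypes: disjoint function support + preferred fragment set + core seq
    prototypes, preferred_sets, cores = [], [], []
    for a in range(spec.n_archetypes):
        proto = np.zeros(spec.n_func)
        proto[a * block:(a + 1) * block] = rng.uniform(0.55, 0.95, size=block)
        prototypes.append(proto)
        preferred_sets.append(frozenset(
            rng.choice(len(FRAGMENT_LIBRARY), size=spec.preferred_fragments,
                       replace=False).tolist()))
        cores.append("".join(rng.choice(list(AMINO_ACIDS),
                                        size=spec.sequence_length)))

    # proteins
    proteins: list[ProteinFunctionVector] = []
    protein_archetype: dict[str, int] = {}
    width = len(str(spec.n_proteins))
    for i in range(spec.n_proteins):
        a = int(rng.integers(spec.n_archetypes))
        scores = np.clip(prototypes[a] + rng.normal(0.0, spec.noise_sd,
                                                    size=spec.n_func), 0.0, 1.0)
        seq = list(cores[a])
        for pos in range(len(seq)):
            if rng.random() < spec.substitution_rate:
                seq[pos] = AMINO_ACIDS[int(rng.integers(20))]
        pid = f"P{i:0{width}d}"
        proteins.append(ProteinFunctionVector(pid, scores, "".join(seq)))
        protein_archetype[pid] = a

    # molecules: chains of library fragments, unique canonical SMILES preferred
    molecules: list[MolGraph] = []
    molecule_fragments: dict[str, tuple[int, ...]] = {}
    seen_smiles: set[str] = set()
    mwidth = len(str(spec.n_molecules))
    lo, hi = spec.fragments_per_molecule
    for i in range(spec.n_molecules):
        mid = f"M{i:0{mwidth}d}"
        for _ in range(50):
            k = int(rng.integers(lo, hi + 1))
            frags = tuple(int(rng.integers(len(FRAGMENT_LIBRARY)))
                          for _ in range(k))
            smiles = "".join(FRAGMENT_LIBRARY[f] for f in frags)
            graph = parse_smiles(smiles, mid)
            if graph.smiles not in seen_smiles:
                break
        seen_smiles.add(graph.smiles)
        molecules.append(graph)
        molecule_fragments[mid] = frags

    # ground truth binding matrix
    true_binding = np.zeros((spec.n_proteins, spec.n_molecules), dtype=bool)
    for pi, prot in enumerate(proteins):
        pref = preferred_sets[protein_archetype[prot.protein_id]]
        for mi, mol in enumerate(molecules):
            true_binding[pi, mi] = binds(molecule_fragments[mol.mol_id], pref)

    # measured activity records (optionally biased toward binders), with flips
    records: list[ActivityRecord] = []
    flipped: set[tuple[str, str]] = set()
    n_rec = min(spec.records_per_protein, spec.n_molecules)
    for pi, prot in enumerate(proteins):
        if spec.positive_record_fraction is None:
            chosen = rng.choice(spec.n_molecules, size=n_rec, replace=False)
        else:
            binders = np.flatnonzero(true_binding[pi])
            nonbinders = np.flatnonzero(~true_binding[pi])
            n_pos = min(int(round(spec.positive_record_fraction * n_rec)),
                        len(binders))
            n_neg = min(n_rec - n_pos, len(nonbinders))
            chosen = np.concatenate([
                rng.choice(binders, size=n_pos, replace=False),
                rng.choice(nonbinders, size=n_neg, replace=False)])
        for mi in np.sort(chosen):
            mol = molecules[int(mi)]
            label = bool(true_binding[pi, int(mi)])
            if rng.random() < spec.label_flip_rate:
                label = not label
                flipped.add((prot.protein_id, mol.mol_id))
            um = _sample_affinity(
                rng, spec.active_affinity_um if label else spec.inactive_affinity_um)
            unit, factor = _UNITS[int(rng.choice(len(_UNITS), p=[0.6, 0.3, 0.1]))]
            metric = _METRICS[int(rng.integers(len(_METRICS)))]
            records.append(ActivityRecord(prot.protein_id, mol.mol_id, metric,
                                          um / factor, unit, source="synthetic"))

    return SyntheticWorld(spec, proteins, molecules, protein_archetype,
                          molecule_fragments, preferred_sets, records,
                          true_binding, flipped)


@dataclass
class WorldView:
    """A subset of a world's proteins and their records (shared molecules)."""

    proteins: list[ProteinFunctionVector]
    molecules: list[MolGraph]
    records: list[ActivityRecord]
    protein_ids: set[str]


def zero_shot_holdout(world: SyntheticWorld,
                      held_protein_count: int) -> tuple[WorldView, WorldView]:
    """Hold entire proteins out of training (the zero-shot scenario).

    The held proteins are taken (deterministically) from the archetype with
    the most proteins, so transfer from same-archetype training proteins
    remains possible; ALL their records move to the test side, leaving zero
    training actives for them. Holding out a whole archetype removes the
    transfer signal by construction and is warned about.
    """
    if held_protein_count == 0:
        return (WorldView(world.proteins, world.molecules, world.records,
                          {p.protein_id for p in world.proteins}),
                WorldView([], world.molecules, [], set()))
    by_arch: dict[int, list[str]] = {}
    for pid, a in world.protein_archetype.items():
        by_arch.setdefault(a, []).append(pid)
    arch = max(sorted(by_arch), key=lambda a: len(by_arch[a]))
    held = sorted(by_arch[arch])[:held_protein_count]
    if len(held) == len(by_arch[arch]):
        logger.warning("holding out the entire archetype %d: the transfer "
                       "signal is removed by construction", arch)
    held_set = set(held)
    train_prot = [p for p in world.proteins if p.protein_id not in held_set]
    test_prot = [p for p in world.proteins if p.protein_id in held_set]
    train_rec = [r for r in world.records if r.protein_id not in held_set]
    test_rec = [r for r in world.records if r.protein_id in held_set]
    return (WorldView(train_prot, world.molecules, train_rec,
                      {p.protein_id for p in train_prot}),
            WorldView(test_prot, world.molecules, test_rec, held_set))


def write_world_files(world: SyntheticWorld, outdir: str | Path) -> dict[str, Path]:
    """Emit the file formats the real pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": outdir / "compounds.csv",
        "fasta": outdir / "proteins.fasta",
        "function_scores": outdir / "function_scores.csv",
        "activity": outdir / "activity.csv",
    }
    with open(paths["compounds"], "w") as fh:
        fh.write("mol_id,smiles\n")
        for m in world.molecules:
            fh.write(f"{m.mol_id},{m.smiles}\n")
    with open(paths["fasta"], "w") as fh:
        for p in world.proteins:
            fh.write(f">{p.protein_id} archetype="
                     f"{world.protein_archetype[p.protein_id]}\n{p.sequence}\n")
    write_function_vectors(world.proteins, paths["function_scores"])
    write_activity_csv(world.records, paths["activity"])
    return paths


def expected_active_fraction(spec: WorldSpec, world: SyntheticWorld) -> float:
    """Compatibility-matrix-implied fraction of truly binding pairs.

    Enumerates archetype x molecule compatibility exactly and weights by the
    realised archetype counts; an independent check on ``true_binding``.
    """
    arch_counts = np.bincount(list(world.protein_archetype.values()),
                              minlength=spec.n_archetypes)
    total = 0.0
    for a, pref in enumerate(world.archetype_preferred):
        frac = np.mean([binds(world.molecule_fragments[m.mol_id], pref)
                        for m in world.molecules])
        total += arch_counts[a] * frac
    return total / max(arch_counts.sum(), 1)
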