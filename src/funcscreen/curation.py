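"""Activity-record curation: unit normalisation, the 50 uM labeling rule,
decoy sampling and scaffold-balanced dataset splitting.

Binary labels follow the micromolar-cutoff convention common in large-scale
binder classification: a protein-compound pair is *active* when every reported
affinity metric (Ki, IC50, EC50, Kd) lies below the cutoff (default 50 uM),
*inactive* when every metric lies above it, and *ambiguous* (excluded from
training, with a log record) when metrics disagree across the cutoff or hit
it exactly. Decoys are assumed negatives sampled per protein from compounds
with no measured record against that protein.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import MolGraph, Scaffold, murcko_scaffold

logger = logging.getLogger(__name__)

METRICS = ("KI", "IC50", "EC50", "KD")
# exact powers of ten to micromolar
_UNIT_TO_UM = {"M": 1e6, "mM": 1e3, "uM": 1.0, "nM": 1e-3, "pM": 1e-6}
DEFAULT_CUTOFF_UM = 50.0
PARTITIONS = ("train", "val", "test")


class CurationError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityRecord:
    protein_id: str
    mol_id: str
    metric: str
    value: float
    unit: str
    source: str = ""

    def __post_init__(self):
        if self.metric not in METRICS:
            raise CurationError(f"unknown metric {self.metric!r} "
                                f"({self.protein_id}, {self.mol_id})")
        if self.unit not in _UNIT_TO_UM:
            raise CurationError(f"unknown unit {self.unit!r} "
                                f"({self.protein_id}, {self.mol_id})")
        if not self.value > 0:
            raise CurationError(f"non-positive value {self.value} "
                                f"({self.protein_id}, {self.mol_id})")


@dataclass(frozen=True)
class LabeledPair:
    protein_id: str
    mol_id: str
    label: str        # active | inactive | decoy
    provenance: str   # measured | assumed_negative

    def __post_init__(self):
        if self.label not in ("active", "inactive", "decoy"):
            raise CurationError(f"bad label {self.label!r}")
        if self.provenance not in ("measured", "assumed_negative"):
            raise CurationError(f"bad provenance {self.provenance!r}")
        if self.label == "decoy" and self.provenance != "assumed_negative":
            raise CurationError("decoys must have provenance assumed_negative")


@dataclass(frozen=True)
class SplitAssignment:
    assignment: Mapping[str, str]  # mol_id -> train | val | test
    seed: int
    fractions: tuple[float, float, float]

    def partition(self, name: str) -> list[str]:
        return sorted(m for m, p in self.assignment.items() if p == name)


def normalize_affinity(value: float, unit: str) -> float:
    """Convert an affinity value to micromolar (exact power-of-ten factors)."""
    if unit not in _UNIT_TO_UM:
        raise CurationError(f"unknown unit {unit!r}")
    return value * _UNIT_TO_UM[unit]


def label_records(records: Sequence[ActivityRecord],
                  cutoff_um: float = DEFAULT_CUTOFF_UM) -> str:
    """Label one (protein, compound) pair from all of its affinity records.

    Returns ``"active"`` (all metrics below cutoff), ``"inactive"`` (all
    above) or ``"ambiguous"`` (metrics straddle the cutoff, or any metric sits
    exactly on it). Order of records is irrelevant.
    """
    if not records:
        raise CurationError("label_records requires at least one record")
    um = [normalize_affinity(r.value, r.unit) for r in records]
    if any(v == cutoff_um for v in um):
        return "ambiguous"
    below = any(v < cutoff_um for v in um)
    above = any(v > cutoff_um for v in um)
    if below and above:
        return "ambiguous"
    return "active" if below else "inactive"


def label_activity_table(records: Iterable[ActivityRecord],
                         cutoff_um: float = DEFAULT_CUTOFF_UM,
                         ) -> tuple[list[LabeledPair], list[tuple[str, str]]]:
    """Label every (protein, compound) pair in a record table.

    Returns (labeled pairs, ambiguous pairs). Ambiguous pairs are excluded
    from the labeled output and logged; pairs are unique in the output.
    """
    grouped: dict[tuple[str, str], list[ActivityRecord]] = defaultdict(list)
    for r in records:
        grouped[(r.protein_id, r.mol_id)].append(r)
    pairs: list[LabeledPair] = []
    ambiguous: list[tuple[str, str]] = []
    for (pid, mid), recs in grouped.items():
        lab = label_records(recs, cutoff_um)
        if lab == "ambiguous":
            ambiguous.append((pid, mid))
        else:
            pairs.append(LabeledPair(pid, mid, lab, "measured"))
    if ambiguous:
        logger.info("excluded %d ambiguous pairs at cutoff %.3g uM",
                    len(ambiguous), cutoff_um)
    return pairs, ambiguous


def add_screening_inactives(pairs: list[LabeledPair],
                            inactive_pairs: Iterable[tuple[str, str]],
                            per_protein_cap: int = 2000) -> list[LabeledPair]:
    """Merge screening-assay inactives (measured label-0), capped per protein.

    Mirrors ingesting bioassay inactives at up to ``per_protein_cap``
    compounds per protein; pairs already present are skipped.
    """
    seen = {(p.protein_id, p.mol_id) for p in pairs}
    counts: dict[str, int] = defaultdict(int)
    for p in pairs:
        if p.label == "inactive":
            counts[p.protein_id] += 1
    out = list(pairs)
    for pid, mid in inactive_pairs:
        if (pid, mid) in seen or counts[pid] >= per_protein_cap:
            continue
        out.append(LabeledPair(pid, mid, "inactive", "measured"))
        seen.add((pid, mid))
        counts[pid] += 1
    return out


def sample_decoys(actives: Sequence[LabeledPair],
                  compound_pool: Sequence[str],
                  measured_pairs: Iterable[tuple[str, str]],
                  ratio: float = 1.0,
                  seed: int = 0) -> list[LabeledPair]:
    """Sample assumed-negative decoys per protein.

    For each protein with ``k`` actives, draw ``round(ratio * k)`` compounds
    uniformly (seeded, without replacement) from ``compound_pool`` excluding
    every compound with a measured record against that protein. If a
    protein's eligible pool is exhausted, all available compounds are taken
    and the shortfall is logged.
    """
    measured: dict[str, set[str]] = defaultdict(set)
    for pid, mid in measured_pairs:
        measured[pid].add(mid)
    per_protein: dict[str, int] = defaultdict(int)
    for p in actives:
        if p.label != "active":
            raise CurationError("sample_decoys expects active pairs only")
        per_protein[p.protein_id] += 1
    pool = sorted(set(compound_pool))
    rng = np.random.default_rng(seed)
    decoys: list[LabeledPair] = []
    for pid in sorted(per_protein):
        want = int(round(ratio * per_protein[pid]))
        if want == 0:
            continue
        eligible = [m for m in pool if m not in measured[pid]]
        if len(eligible) < want:
            logger.warning("decoy pool exhausted for %s: want %d, have %d",
                           pid, want, len(eligible))
            chosen = eligible
        else:
            chosen = [eligible[i] for i in
                      rng.choice(len(eligible), size=want, replace=False)]
        decoys += [LabeledPair(pid, m, "decoy", "assumed_negative")
                   for m in sorted(chosen)]
    return decoys


def scaffold_balanced_split(molecules: Sequence[MolGraph],
                            fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                            seed: int = 0) -> SplitAssignment:
    """Scaffold-balanced train/val/test split.

    Molecules are grouped by Bemis-Murcko scaffold; a scaffold never spans
    partitions. Groups larger than half the test-set target go to train
    outright; the remaining groups are shuffled (seeded) and placed greedily
    into the partition currently furthest below its target count.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise CurationError(f"fractions must sum to 1, got {fractions}")
    groups: dict[str, list[str]] = defaultdict(list)
    for mol in molecules:
        groups[murcko_scaffold(mol).scaffold_smiles].append(mol.mol_id)

    n = len(molecules)
    n_active_partitions = sum(1 for f in fractions if f > 0)
    if len(groups) < n_active_partitions:
        logger.warning("fewer scaffold groups (%d) than partitions; "
                       "placing everything in train", len(groups))
        return SplitAssignment({m.mol_id: "train" for m in molecules},
                               seed, tuple(fractions))

    targets = [f * n for f in fractions]
    counts = [0.0, 0.0, 0.0]
    assignment: dict[str, str] = {}

    # groups bigger than half the test target are pinned to train; the cutoff
    # is floored at 1 so singleton scaffolds stay placeable at tiny scale
    big_cut = max(targets[2] / 2.0, 1.0) if fractions[2] > 0 else float("inf")
    keys = sorted(groups)
    big = [k for k in keys if len(groups[k]) > big_cut]
    small = [k for k in keys if len(groups[k]) <= big_cut]
    for k in big:
        for m in groups[k]:
            assignment[m] = "train"
        counts[0] += len(groups[k])

    rng = np.random.default_rng(seed)
    rng.shuffle(small)
    for k in small:
        deficits = [targets[i] - counts[i] if fractions[i] > 0 else -np.inf
                    for i in range(3)]
        part = int(np.argmax(deficits))  # ties -> train before val before test
        for m in groups[k]:
            assignment[m] = PARTITIONS[part]
        counts[part] += len(groups[k])
    return SplitAssignment(assignment, seed, tuple(fractions))


# ---------------------------------------------------------------------------
# CSV interchange

def read_activity_csv(path: str | Path) -> list[ActivityRecord]:
    df = pd.read_csv(path, comment="#", dtype={"protein_id": str, "mol_id": str})
    need = {"protein_id", "mol_id", "metric", "value", "unit"}
    if not need.issubset(df.columns):
        raise CurationError(f"{path}: expected columns {sorted(need)}")
    return [ActivityRecord(r.protein_id, r.mol_id, r.metric, float(r.value),
                           r.unit, getattr(r, "source", "") or "")
            for r in df.itertuples(index=False)]


def write_activity_csv(records: Iterable[ActivityRecord], path: str | Path) -> None:
    pd.DataFrame([{"protein_id": r.protein_id, "mol_id": r.mol_id,
                   "metric": r.metric, "value": r.value, "unit": r.unit,
                   "source": r.source} for r in records]).to_csv(path, index=False)


def write_labeled_pairs(pairs: Iterable[LabeledPair], path: str | Path) -> None:
    pd.DataFrame([{"protein_id": p.protein_id, "mol_id": p.mol_id,
                   "label": p.label, "provenance": p.provenance}
                  for p in pairs]).to_csv(path, index=False)


def read_labeled_pairs(path: str | Path) -> list[LabeledPair]:
    df = pd.read_csv(path, comment="#", dtype=str)
    return [LabeledPair(r.protein_id, r.mol_id, r.label, r.provenance)
            for r in df.itertuples(index=False)]


def write_split(split: SplitAssignment, path: str | Path) -> None:
    pd.DataFrame(sorted(split.assignment.items()),
                 columns=["mol_id", "partition"]).to_csv(path, index=False)


def read_split(path: str | Path,
               fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
               seed: int = -1) -> SplitAssignment:
    df = pd.read_csv(path, comment="#", dtype=str)
    return SplitAssignment(dict(zip(df.mol_id, df.partition)), seed, fractions)
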