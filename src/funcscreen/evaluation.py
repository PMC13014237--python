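"""Virtual-screening evaluation: enrichment factors, threshold confusion
analysis, and the train/test similarity leakage filter.

The enrichment factor at fraction alpha is the ratio of actives retrieved in
the top ``ceil(alpha * N)`` ranks to the count expected under random ranking
(``alpha * total actives``): EF = 1 for a random ranking, 1/alpha at best.
The leakage filter scores each test (protein, compound) pair against every
train pair by the product of global protein sequence identity and compound
Tanimoto similarity, removing test pairs whose best product exceeds a
threshold (conventionally 0.9 / 0.7 / 0.5), with an exact-duplicate mode
based on canonical-SMILES equality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .chem import Fingerprint, tanimoto

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ScreenResult:
    """A ranked screening run for one protein.

    Entries are sorted by probability descending with mol_id-ascending
    tiebreak at construction; ranks are 1..N in that order.
    """

    protein_id: str
    mol_ids: tuple[str, ...]
    probabilities: np.ndarray
    labels: np.ndarray | None = None  # 1 = active, 0 = not; optional

    @classmethod
    def from_scores(cls, protein_id: str, mol_ids: Sequence[str],
                    probabilities: Sequence[float],
                    labels: Sequence[int] | None = None) -> "ScreenResult":
        probs = np.asarray(probabilities, dtype=np.float64)
        order = sorted(range(len(mol_ids)),
                       key=lambda i: (-probs[i], mol_ids[i]))
        return cls(
            protein_id=protein_id,
            mol_ids=tuple(mol_ids[i] for i in order),
            probabilities=probs[order],
            labels=(np.asarray(labels, dtype=np.int64)[order]
                    if labels is not None else None),
        )

    @property
    def n(self) -> int:
        return len(self.mol_ids)


@dataclass
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float | None  # None when no predicted positives
    recall: float
    f1: float | None


@dataclass
class EvalReport:
    ef: dict[float, float]
    confusion: dict[float, Confusion]
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "ef": {str(a): v for a, v in self.ef.items()},
            "confusion": {str(t): vars(c) for t, c in self.confusion.items()},
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def enrichment_factor(result: ScreenResult, alpha: float) -> float:
    """EF at fraction ``alpha``: (actives in top ceil(alpha*N)) / (alpha * actives)."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    if result.labels is None:
        raise ValueError("enrichment factor requires known labels")
    total_actives = int(result.labels.sum())
    if total_actives == 0:
        raise ValueError(f"EF undefined: no actives for {result.protein_id!r}")
    k = math.ceil(alpha * result.n)
    hits = int(result.labels[:k].sum())
    return hits / (alpha * total_actives)


def confusion_at_threshold(result: ScreenResult, tau: float) -> Confusion:
    """Confusion counts with predicted-positive = probability >= tau (closed)."""
    if result.labels is None:
        raise ValueError("confusion requires known labels")
    pred = result.probabilities >= tau
    y = result.labels.astype(bool)
    tp = int(np.count_nonzero(pred & y))
    fp = int(np.count_nonzero(pred & ~y))
    tn = int(np.count_nonzero(~pred & ~y))
    fn = int(np.count_nonzero(~pred & y))
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision is not None and (precision + recall) > 0 else None)
    return Confusion(tp, fp, tn, fn, precision, recall, f1)


def evaluate(result: ScreenResult,
             ef_fractions: Sequence[float] = (0.01, 0.05, 0.1),
             thresholds: Sequence[float] = (0.45, 0.5),
             metadata: dict | None = None) -> EvalReport:
    """Full screening report: EF at each fraction, confusion at each threshold."""
    return EvalReport(
        ef={a: enrichment_factor(result, a) for a in ef_fractions},
        confusion={t: confusion_at_threshold(result, t) for t in thresholds},
        metadata=metadata or {},
    )


# ---------------------------------------------------------------------------
# sequence identity and the similarity leakage filter

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def global_identity(seq_a: str, seq_b: str) -> float:
    """Global (Needleman-Wunsch, BLOSUM62, gap open 10 / extend 0.5) identity.

    Identity = identical aligned positions / full alignment length, gap
    columns included. 'X' never counts as identical.
    """
    for name, s in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not s:
            raise ValueError(f"{name} is empty")
        bad = set(s.upper()) - AMINO_ALPHABET
        if bad:
            raise ValueError(f"{name} contains invalid residues {sorted(bad)}")
    aln = _make_aligner().align(seq_a.upper(), seq_b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    identical = sum(1 for x, y in zip(row_a, row_b)
                    if x == y and x not in ("-", "X"))
    return identical / len(row_a)


@dataclass(frozen=True)
class PairSimilarity:
    """Best train-pair match for one test pair under the product score."""

    test_pair: tuple[str, str]
    train_pair: tuple[str, str] | None
    identity: float
    tanimoto: float

    @property
    def score(self) -> float:
        return self.identity * self.tanimoto


def filter_similar_pairs(
    test_pairs: Sequence[tuple[str, str]],
    train_pairs: Sequence[tuple[str, str]],
    threshold: float,
    sequences: Mapping[str, str],
    fingerprints: Mapping[str, Fingerprint],
    smiles: Mapping[str, str] | None = None,
    mode: str = "product",
) -> tuple[list[tuple[str, str]], list[PairSimilarity]]:
    """Remove test pairs too similar to any train pair.

    ``mode="product"``: a test pair (p, m) is removed iff some train pair
    (p', m') has identity(p, p') * tanimoto(m, m') > threshold.
    ``mode="exact"``: removed iff the compound's canonical SMILES equals a
    train compound's (requires ``smiles``; threshold is ignored).

    Returns (retained test pairs, removed pairs with their best match).
    """
    if mode not in ("product", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exact":
        if smiles is None:
            raise ValueError("exact mode requires canonical SMILES")
        for _, m in list(test_pairs) + list(train_pairs):
            if m not in smiles:
                raise KeyError(f"missing SMILES for compound {m!r}")
        train_smiles = {smiles[m] for _, m in train_pairs}
        retained, removed = [], []
        for pair in test_pairs:
            if smiles[pair[1]] in train_smiles:
                removed.append(PairSimilarity(pair, None, 1.0, 1.0))
            else:
                retained.append(pair)
        return retained, removed

    for p, _ in list(test_pairs) + list(train_pairs):
        if p not in sequences:
            raise KeyError(f"missing sequence for protein {p!r}")
    for _, m in list(test_pairs) + list(train_pairs):
        if m not in fingerprints:
            raise KeyError(f"missing fingerprint for compound {m!r}")

    test_prots = sorted({p for p, _ in test_pairs})
    train_prots = sorted({p for p, _ in train_pairs})
    test_mols = sorted({m for _, m in test_pairs})
    train_mols = sorted({m for _, m in train_pairs})
    ident = {(a, b): (1.0 if sequences[a] == sequences[b]
                      else global_identity(sequences[a], sequences[b]))
             for a in test_prots for b in train_prots}
    tani = {(a, b): tanimoto(fingerprints[a], fingerprints[b])
            for a in test_mols for b in train_mols}

    tp_idx = np.array([train_prots.index(p) for p, _ in train_pairs])
    tm_idx = np.array([train_mols.index(m) for _, m in train_pairs])
    retained, removed = [], []
    for pair in test_pairs:
        p, m = pair
        ivec = np.array([ident[(p, tp)] for tp in train_prots])[tp_idx]
        tvec = np.array([tani[(m, tm)] for tm in train_mols])[tm_idx]
        scores = ivec * tvec
        best = int(np.argmax(scores)) if len(scores) else -1
        if best >= 0 and scores[best] > threshold:
            removed.append(PairSimilarity(pair, tuple(train_pairs[best]),
                                          float(ivec[best]), float(tvec[best])))
        else:
            retained.append(pair)
    return retained, removed


def write_removed_pairs_tsv(removed: Sequence[PairSimilarity],
                            path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tmol_id\tbest_train_protein\tbest_train_mol\t"
                 "similarity\tidentity\ttanimoto\n")
        for r in removed:
            tp = r.train_pair or ("", "")
            fh.write(f"{r.test_pair[0]}\t{r.test_pair[1]}\t{tp[0]}\t{tp[1]}\t"
                     f"{r.score:.6f}\t{r.identity:.6f}\t{r.tanimoto:.6f}\n")
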