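"""Protein-side representation: molecular-function score vectors.

Proteins are represented solely by a fixed-length vector of predicted
molecular-function class scores in [0, 1] (489 classes for the standard
sequence-based function predictor; length is configurable and the synthetic
world uses a smaller one). The vector is consumed through a learned linear
projection into the fusion space. Function prediction itself is an input
contract, not reimplemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

DEFAULT_N_FUNC = 489
CLIP_EPS = 1e-6  # float round-off tolerance outside [0, 1]


class FunctionScoreError(ValueError):
    pass


@dataclass
class ProteinFunctionVector:
    protein_id: str
    scores: np.ndarray  # (n_func,), each in [0, 1]
    sequence: str | None = None

    @property
    def n_func(self) -> int:
        return self.scores.shape[0]


@dataclass
class FunctionProjection:
    """Learned linear map W (n_func x d_embed) and bias b (d_embed)."""

    weight: np.ndarray
    bias: np.ndarray

    def __post_init__(self):
        if self.weight.ndim != 2 or self.bias.ndim != 1:
            raise FunctionScoreError("weight must be 2-D and bias 1-D")
        if self.weight.shape[1] != self.bias.shape[0]:
            raise FunctionScoreError(
                f"weight columns ({self.weight.shape[1]}) != bias length "
                f"({self.bias.shape[0]})")
        if not (np.all(np.isfinite(self.weight)) and np.all(np.isfinite(self.bias))):
            raise FunctionScoreError("non-finite projection parameters")


def _validate_scores(protein_id: str, raw: np.ndarray, row: int) -> np.ndarray:
    if np.any(raw < -CLIP_EPS) or np.any(raw > 1.0 + CLIP_EPS):
        bad = raw[(raw < -CLIP_EPS) | (raw > 1.0 + CLIP_EPS)][0]
        raise FunctionScoreError(
            f"row {row} (protein {protein_id!r}): score {bad} outside [0, 1]")
    return np.clip(raw, 0.0, 1.0)


def load_function_vectors(path: str | Path,
                          n_func: int | None = None) -> list[ProteinFunctionVector]:
    """Load a function-score CSV (header ``protein_id,f_1..f_n``).

    Values within ``CLIP_EPS`` of [0, 1] are clipped in; larger violations and
    duplicate protein ids are data errors naming the offending row.
    """
    df = pd.read_csv(path, comment="#")
    if df.columns[0] != "protein_id":
        raise FunctionScoreError(f"{path}: first column must be protein_id")
    width = df.shape[1] - 1
    if n_func is not None and width != n_func:
        raise FunctionScoreError(
            f"{path}: expected {n_func} score columns, found {width}")
    if df["protein_id"].duplicated().any():
        dup = df["protein_id"][df["protein_id"].duplicated()].iloc[0]
        raise FunctionScoreError(f"{path}: duplicate protein_id {dup!r}")
    out = []
    for row_idx, row in enumerate(df.itertuples(index=False), start=1):
        pid = str(row[0])
        raw = np.asarray(row[1:], dtype=np.float64)
        if raw.shape[0] != width or np.any(np.isnan(raw)):
            raise FunctionScoreError(f"{path}: row {row_idx} has a missing value")
        out.append(ProteinFunctionVector(pid, _validate_scores(pid, raw, row_idx)))
    return out


def write_function_vectors(vectors: Iterable[ProteinFunctionVector],
                           path: str | Path) -> None:
    vectors = list(vectors)
    n = vectors[0].n_func
    cols = ["protein_id"] + [f"f_{i + 1}" for i in range(n)]
    df = pd.DataFrame(
        [[v.protein_id] + list(v.scores) for v in vectors], columns=cols)
    df.to_csv(path, index=False)


def project_function(f: ProteinFunctionVector,
                     proj: FunctionProjection) -> np.ndarray:
    """Project function scores into the fusion space: ``f @ W + b``."""
    if f.n_func != proj.weight.shape[0]:
        raise FunctionScoreError(
            f"function vector length {f.n_func} != projection rows "
            f"{proj.weight.shape[0]}")
    return f.scores @ proj.weight + proj.bias


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA -> {protein_id: sequence}; id = first header token."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FunctionScoreError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def attach_sequences(vectors: Iterable[ProteinFunctionVector],
                     sequences: dict[str, str]) -> None:
    """Attach FASTA sequences (matched by id) to function vectors, in place."""
    for v in vectors:
        if v.protein_id in sequences:
            v.sequence = sequences[v.protein_id]
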