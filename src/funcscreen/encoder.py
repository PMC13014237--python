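"""Directed bond-level message-passing molecular encoder (Chemprop-style).

Each directed bond u->v carries a hidden state initialised from the source
atom's features concatenated with the bond's features. For ``depth`` steps a
bond aggregates (sums) the states of incoming bonds w->u excluding its own
reverse, passes them through a learned linear map and activation with a skip
connection to its initial state. Bond states are then pooled onto atoms,
projected, and read out by sum or mean into a fixed-length molecule embedding.

An optional additive "functional prompt" vector (an externally supplied
hidden-size vector, e.g. from a knowledge-graph-pretrained model) can be added
to the initial projections before message passing; it is an input here, never
learned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .chem import MolGraph, N_ATOM_FEATURES, N_BOND_FEATURES


@dataclass(frozen=True)
class EncoderConfig:
    hidden_dim: int = 64
    depth: int = 3
    readout: str = "sum"  # or "mean"
    activation: str = "relu"
    prompt_enabled: bool = False

    def __post_init__(self):
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.readout not in ("sum", "mean"):
            raise ValueError(f"unknown readout {self.readout!r}")
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")


@dataclass(frozen=True)
class MolEmbedding:
    vector: np.ndarray
    mol_id: str


@dataclass
class GraphBatch:
    """A disjoint union of molecular graphs with flat index arrays."""

    atom_feats: np.ndarray     # (A, N_ATOM_FEATURES)
    bond_feats: np.ndarray     # (B, N_BOND_FEATURES)
    bond_src: np.ndarray       # (B,) global atom index
    bond_dst: np.ndarray       # (B,)
    rev_index: np.ndarray      # (B,)
    atom_mol: np.ndarray       # (A,) molecule index per atom
    n_mols: int
    mol_ids: list[str]

    @classmethod
    def from_graphs(cls, graphs: Sequence[MolGraph]) -> "GraphBatch":
        atom_feats, bond_feats = [], []
        bond_src, bond_dst, rev_index, atom_mol = [], [], [], []
        a_off = b_off = 0
        for i, g in enumerate(graphs):
            atom_feats.append(g.atoms)
            bond_feats.append(g.bonds)
            bond_src.append(g.bond_src + a_off)
            bond_dst.append(g.bond_dst + a_off)
            rev_index.append(g.rev_index + b_off)
            atom_mol.append(np.full(g.n_atoms, i, dtype=np.int64))
            a_off += g.n_atoms
            b_off += g.n_directed_bonds
        cat = lambda parts, w: (np.concatenate(parts) if parts else
                                np.zeros((0, w)) if w else np.zeros(0, dtype=np.int64))
        return cls(
            atom_feats=np.concatenate(atom_feats) if atom_feats else np.zeros((0, N_ATOM_FEATURES)),
            bond_feats=np.concatenate(bond_feats) if bond_feats else np.zeros((0, N_BOND_FEATURES)),
            bond_src=np.concatenate(bond_src) if bond_src else np.zeros(0, dtype=np.int64),
            bond_dst=np.concatenate(bond_dst) if bond_dst else np.zeros(0, dtype=np.int64),
            rev_index=np.concatenate(rev_index) if rev_index else np.zeros(0, dtype=np.int64),
            atom_mol=np.concatenate(atom_mol) if atom_mol else np.zeros(0, dtype=np.int64),
            n_mols=len(graphs),
            mol_ids=[g.mol_id for g in graphs],
        )

    @property
    def n_atoms(self) -> int:
        return self.atom_feats.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bond_feats.shape[0]


def init_encoder_params(config: EncoderConfig,
                        rng: np.random.Generator) -> dict[str, Tensor]:
    """Glorot-uniform initialised encoder weights as a named parameter dict."""
    h = config.hidden_dim
    fin_bond = N_ATOM_FEATURES + N_BOND_FEATURES
    fin_atom = N_ATOM_FEATURES + h
    return {
        "enc.W_i": ag.tensor(ag.glorot_uniform(rng, fin_bond, h)),
        "enc.b_i": ag.tensor(np.zeros(h)),
        "enc.W_h": ag.tensor(ag.glorot_uniform(rng, h, h)),
        "enc.W_o": ag.tensor(ag.glorot_uniform(rng, fin_atom, h)),
        "enc.b_o": ag.tensor(np.zeros(h)),
    }


def encode_batch(batch: GraphBatch, params: dict[str, Tensor],
                 config: EncoderConfig,
                 prompt: np.ndarray | None = None) -> Tensor:
    """Encode a batch of graphs into an ``(n_mols, hidden_dim)`` tensor.

    Deterministic given weights and graphs; permutation-invariant because all
    aggregations are sums.
    """
    h_dim = config.hidden_dim
    if params["enc.W_i"].shape != (N_ATOM_FEATURES + N_BOND_FEATURES, h_dim):
        raise ValueError("encoder weights do not match config dimensions")
    if prompt is not None:
        prompt = np.asarray(prompt, dtype=np.float64)
        if prompt.shape != (h_dim,):
            raise ValueError(f"prompt must have length {h_dim}")
        if not config.prompt_enabled:
            raise ValueError("prompt supplied but prompt_enabled is False")

    A = batch.n_atoms
    atom_const = ag.constant(batch.atom_feats)

    if config.depth == 0 or batch.n_bonds == 0:
        # bag-of-atom-projections: no bond information enters the readout
        atom_in = ag.concat([atom_const, ag.constant(np.zeros((A, h_dim)))], axis=1)
    else:
        bond_in = np.concatenate(
            [batch.atom_feats[batch.bond_src], batch.bond_feats], axis=1)
        pre = ag.add(ag.matmul(ag.constant(bond_in), params["enc.W_i"]),
                     params["enc.b_i"])
        if config.prompt_enabled and prompt is not None:
            pre = ag.add(pre, ag.constant(prompt))
        h0 = ag.relu(pre)
        h = h0
        for _ in range(config.depth):
            incoming = ag.segment_sum(h, batch.bond_dst, A)  # per-atom inbox
            msg = ag.add(ag.take_rows(incoming, batch.bond_src),
                         ag.scale(ag.take_rows(h, batch.rev_index), -1.0))
            h = ag.relu(ag.add(h0, ag.matmul(msg, params["enc.W_h"])))
        atom_inbox = ag.segment_sum(h, batch.bond_dst, A)
        atom_in = ag.concat([atom_const, atom_inbox], axis=1)

    atom_state = ag.relu(ag.add(ag.matmul(atom_in, params["enc.W_o"]),
                                params["enc.b_o"]))
    mol = ag.segment_sum(atom_state, batch.atom_mol, batch.n_mols)
    if config.readout == "mean":
        counts = np.bincount(batch.atom_mol, minlength=batch.n_mols).astype(float)
        counts[counts == 0] = 1.0
        mol = ag.mul(mol, ag.constant(1.0 / counts[:, None]))
    return mol


def encode_molecule(graph: MolGraph, params: dict[str, Tensor],
                    config: EncoderConfig,
                    prompt: np.ndarray | None = None) -> MolEmbedding:
    """Encode one molecule into a fixed-length embedding."""
    out = encode_batch(GraphBatch.from_graphs([graph]), params, config, prompt)
    vec = np.array(out.data[0])
    if not np.all(np.isfinite(vec)):
        raise FloatingPointError(f"non-finite embedding for {graph.mol_id!r}")
    return MolEmbedding(vector=vec, mol_id=graph.mol_id)
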