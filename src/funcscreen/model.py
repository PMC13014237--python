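"""Fusion model: function-vector conditioning of a molecular-graph encoder,
feed-forward binary classification head, training loop and ensembling.

The protein's molecular-function score vector is linearly projected and fused
with the trainable molecule embedding — by elementwise addition (default; on
pilot comparisons addition slightly outperforms concatenation) or by
concatenation — and passed through feed-forward layers ending in a sigmoid
binding probability. Training minimises binary cross-entropy over labeled
(protein, compound) pairs; decoys enter as label-0 examples exactly like
measured inactives. An ensemble averages member probabilities; members differ
by their scaffold-balanced validation-split seeds and weight seeds.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .chem import MolGraph
from .curation import LabeledPair, scaffold_balanced_split
from .encoder import (EncoderConfig, GraphBatch, MolEmbedding, encode_batch,
                      init_encoder_params)
from .profunc import FunctionProjection, ProteinFunctionVector

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class FusionConfig:
    mode: str = "add"          # add | concat
    ffn_layers: int = 2        # linear layers incl. the output layer
    ffn_hidden: int = 64
    dropout: float = 0.1       # FFN only; always off at inference

    def __post_init__(self):
        if self.mode not in ("add", "concat"):
            raise ValueError(f"unknown fusion mode {self.mode!r}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.ffn_layers < 1:
            raise ValueError("ffn_layers must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    class_handling: str = "none"  # none | pos_weight
    split_seed: int = 0
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.class_handling not in ("none", "pos_weight"):
            raise ValueError(f"unknown class_handling {self.class_handling!r}")


def fuse(h_mol: np.ndarray | MolEmbedding, h_prot: np.ndarray,
         config: FusionConfig) -> np.ndarray:
    """Fuse molecule and projected-protein vectors (add or concat)."""
    if isinstance(h_mol, MolEmbedding):
        h_mol = h_mol.vector
    h_mol = np.asarray(h_mol, dtype=np.float64)
    h_prot = np.asarray(h_prot, dtype=np.float64)
    if config.mode == "add":
        if h_mol.shape != h_prot.shape:
            raise ValueError(
                f"add fusion requires equal dims, got {h_mol.shape} vs {h_prot.shape}")
        return h_mol + h_prot
    return np.concatenate([h_mol, h_prot])


@dataclass
class PairDataset:
    """Labeled (protein, compound) pairs plus entity lookups."""

    pairs: list[tuple[str, str, int]]  # (protein_id, mol_id, binary label)
    proteins: dict[str, ProteinFunctionVector]
    molecules: dict[str, MolGraph]

    @classmethod
    def from_labeled_pairs(cls, labeled: Iterable[LabeledPair],
                           proteins: Iterable[ProteinFunctionVector],
                           molecules: Iterable[MolGraph]) -> "PairDataset":
        prot = {p.protein_id: p for p in proteins}
        mols = {m.mol_id: m for m in molecules}
        pairs = []
        for lp in labeled:
            if lp.protein_id not in prot:
                raise KeyError(f"no function vector for protein {lp.protein_id!r}")
            if lp.mol_id not in mols:
                raise KeyError(f"no structure for compound {lp.mol_id!r}")
            pairs.append((lp.protein_id, lp.mol_id,
                          1 if lp.label == "active" else 0))
        return cls(pairs, prot, mols)

    @property
    def n_func(self) -> int:
        return next(iter(self.proteins.values())).n_func

    def subset(self, mol_ids: set[str]) -> list[tuple[str, str, int]]:
        return [p for p in self.pairs if p[1] in mol_ids]


class BinderModel:
    """One trained (or freshly initialised) binder-classification model.

    Doubles as the checkpoint object: it holds every weight array, all
    configs, the RNG seed it was initialised from and the training log.
    """

    def __init__(self, n_func: int, enc_config: EncoderConfig,
                 fusion_config: FusionConfig, seed: int):
        self.n_func = n_func
        self.enc_config = enc_config
        self.fusion_config = fusion_config
        self.seed = seed
        self.train_log: dict = {}
        rng = np.random.default_rng(seed)
        h = enc_config.hidden_dim
        self.params: dict[str, Tensor] = init_encoder_params(enc_config, rng)
        self.params["proj.W"] = ag.tensor(ag.glorot_uniform(rng, n_func, h))
        self.params["proj.b"] = ag.tensor(np.zeros(h))
        in_dim = h if fusion_config.mode == "add" else 2 * h
        dims = ([in_dim] + [fusion_config.ffn_hidden] * (fusion_config.ffn_layers - 1)
                + [1])
        for i in range(fusion_config.ffn_layers):
            self.params[f"ffn.W{i}"] = ag.tensor(
                ag.glorot_uniform(rng, dims[i], dims[i + 1]))
            self.params[f"ffn.b{i}"] = ag.tensor(np.zeros(dims[i + 1]))

    # -- forward ------------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def projection(self) -> FunctionProjection:
        return FunctionProjection(weight=np.array(self.params["proj.W"].data),
                                  bias=np.array(self.params["proj.b"].data))

    def forward(self, batch: GraphBatch, pair_mol_idx: np.ndarray,
                prot_scores: np.ndarray, training: bool = False,
                dropout_rng: np.random.Generator | None = None,
                prompt: np.ndarray | None = None) -> Tensor:
        """Logits for ``n_pairs`` pairs; ``prot_scores`` is (n_pairs, n_func)."""
        if prot_scores.shape[1] != self.n_func:
            raise ValueError(f"function vector length {prot_scores.shape[1]} "
                             f"!= model n_func {self.n_func}")
        mol = encode_batch(batch, self.params, self.enc_config, prompt)
        h_mol = ag.take_rows(mol, pair_mol_idx)
        h_prot = ag.add(ag.matmul(ag.constant(prot_scores), self.params["proj.W"]),
                        self.params["proj.b"])
        if self.fusion_config.mode == "add":
            x = ag.add(h_mol, h_prot)
        else:
            x = ag.concat([h_mol, h_prot], axis=1)
        p_drop = self.fusion_config.dropout
        for i in range(self.fusion_config.ffn_layers):
            x = ag.add(ag.matmul(x, self.params[f"ffn.W{i}"]),
                       self.params[f"ffn.b{i}"])
            if i < self.fusion_config.ffn_layers - 1:
                x = ag.relu(x)
                if training and p_drop > 0.0:
                    mask = (dropout_rng.random(x.shape) >= p_drop) / (1.0 - p_drop)
                    x = ag.mul(x, ag.constant(mask))
        return x

    def predict_probabilities(self, protein: ProteinFunctionVector,
                              graphs: Sequence[MolGraph]) -> np.ndarray:
        """Inference-mode binding probabilities of one protein vs many compounds."""
        batch = GraphBatch.from_graphs(graphs)
        prot = np.tile(protein.scores, (len(graphs), 1))
        logits = self.forward(batch, np.arange(len(graphs)), prot, training=False)
        return ag.sigmoid(logits).data[:, 0]


def predict_pair(protein: ProteinFunctionVector, graph: MolGraph,
                 model: BinderModel) -> float:
    """Deterministic (dropout-off) binding probability for one pair."""
    return float(model.predict_probabilities(protein, [graph])[0])


@dataclass
class EnsembleModel:
    members: list[BinderModel]
    member_seeds: list[int]

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble requires >= 1 member")
        n_func = {m.n_func for m in self.members}
        if len(n_func) != 1:
            raise ValueError("ensemble members disagree on n_func")

    def predict_probabilities(self, protein: ProteinFunctionVector,
                              graphs: Sequence[MolGraph]) -> np.ndarray:
        out = np.stack([m.predict_probabilities(protein, graphs)
                        for m in self.members])
        return out.mean(axis=0)


def ensemble_predict(ensemble: EnsembleModel, protein: ProteinFunctionVector,
                     graph: MolGraph) -> float:
    """Arithmetic mean of member probabilities for one pair."""
    return float(ensemble.predict_probabilities(protein, [graph])[0])


# ---------------------------------------------------------------------------
# training

def _bce_with_logits(logits: Tensor, labels: np.ndarray,
                     pos_weight: float = 1.0) -> Tensor:
    """Mean binary cross-entropy from logits (numerically stable)."""
    y = labels.reshape(-1, 1).astype(np.float64)
    # loss_i = w*y*softplus(-z) + (1-y)*softplus(z)
    pos = ag.mul(ag.constant(pos_weight * y), ag.softplus(ag.scale(logits, -1.0)))
    neg = ag.mul(ag.constant(1.0 - y), ag.softplus(logits))
    return ag.mean(ag.add(pos, neg))


def _batch_arrays(dataset: PairDataset, pairs: Sequence[tuple[str, str, int]]):
    """Pack a pair list into (GraphBatch of unique mols, pair->mol idx,
    protein score matrix, label vector)."""
    mol_ids = sorted({m for _, m, _ in pairs})
    mol_pos = {m: i for i, m in enumerate(mol_ids)}
    batch = GraphBatch.from_graphs([dataset.molecules[m] for m in mol_ids])
    pair_mol = np.array([mol_pos[m] for _, m, _ in pairs], dtype=np.int64)
    prot = np.stack([dataset.proteins[p].scores for p, _, _ in pairs])
    labels = np.array([y for _, _, y in pairs], dtype=np.float64)
    return batch, pair_mol, prot, labels


def _eval_loss(model: BinderModel, dataset: PairDataset,
               pairs: Sequence[tuple[str, str, int]], pos_weight: float) -> float:
    batch, pair_mol, prot, labels = _batch_arrays(dataset, pairs)
    logits = model.forward(batch, pair_mol, prot, training=False)
    return float(_bce_with_logits(logits, labels, pos_weight).data)


def train(dataset: PairDataset,
          fusion: FusionConfig = FusionConfig(),
          enc: EncoderConfig = EncoderConfig(),
          tc: TrainConfig = TrainConfig()) -> BinderModel:
    """Train one binder model with seeded minibatch Adam on BCE.

    The validation set is a scaffold-balanced 10% (by default) of training
    molecules, controlled by ``tc.split_seed``. Decoys contribute as label-0
    examples identically to measured inactives. Raises on single-class data
    and aborts with a diagnostic if the loss goes non-finite.
    """
    labels_all = np.array([y for _, _, y in dataset.pairs])
    if labels_all.min() == labels_all.max():
        raise ValueError("training data must contain both classes")

    if tc.val_fraction > 0:
        mols = [dataset.molecules[m] for m in
                sorted({m for _, m, _ in dataset.pairs})]
        split = scaffold_balanced_split(
            mols, (1.0 - tc.val_fraction, tc.val_fraction, 0.0),
            seed=tc.split_seed)
        val_mols = set(split.partition("val"))
    else:
        val_mols = set()
    train_pairs = [p for p in dataset.pairs if p[1] not in val_mols]
    val_pairs = [p for p in dataset.pairs if p[1] in val_mols]
    ytr = np.array([y for _, _, y in train_pairs])
    if ytr.min() == ytr.max():
        raise ValueError("training split became single-class; "
                         "adjust val_fraction or split_seed")

    pos_weight = 1.0
    if tc.class_handling == "pos_weight":
        pos_weight = float((ytr == 0).sum() / max((ytr == 1).sum(), 1))

    model = BinderModel(dataset.n_func, enc, fusion, seed=tc.seed)
    rng = np.random.default_rng(tc.seed)
    opt = ag.Adam(model.params, lr=tc.learning_rate)
    epoch_losses: list[float] = []
    idx = np.arange(len(train_pairs))
    for epoch in range(tc.epochs):
        rng.shuffle(idx)
        running, nb = 0.0, 0
        for start in range(0, len(idx), tc.batch_size):
            chunk = [train_pairs[i] for i in idx[start:start + tc.batch_size]]
            batch, pair_mol, prot, labels = _batch_arrays(dataset, chunk)
            opt.zero_grad()
            logits = model.forward(batch, pair_mol, prot, training=True,
                                   dropout_rng=rng)
            loss = _bce_with_logits(logits, labels, pos_weight)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {nb}; "
                    f"lr={tc.learning_rate}, batch_size={tc.batch_size}")
            loss.backward()
            opt.step()
            running += float(loss.data)
            nb += 1
        epoch_losses.append(running / max(nb, 1))
    model.train_log = {
        "epoch_losses": epoch_losses,
        "final_train_loss": _eval_loss(model, dataset, train_pairs, pos_weight),
        "final_val_loss": (_eval_loss(model, dataset, val_pairs, pos_weight)
                           if val_pairs else None),
        "n_train_pairs": len(train_pairs),
        "n_val_pairs": len(val_pairs),
        "pos_weight": pos_weight,
        "train_config": asdict(tc),
    }
    return model


def train_ensemble(dataset: PairDataset, n_members: int = 3,
                   fusion: FusionConfig = FusionConfig(),
                   enc: EncoderConfig = EncoderConfig(),
                   tc: TrainConfig = TrainConfig()) -> EnsembleModel:
    """Ensemble of ``n_members`` models with split seeds seed, seed+1, ..."""
    members, seeds = [], []
    for i in range(n_members):
        tci = TrainConfig(**{**asdict(tc),
                             "seed": tc.seed + i,
                             "split_seed": tc.split_seed + i})
        members.append(train(dataset, fusion, enc, tci))
        seeds.append(tci.split_seed)
    return EnsembleModel(members=members, member_seeds=seeds)


# ---------------------------------------------------------------------------
# checkpoint IO and screening output

def save_checkpoint(model: BinderModel, path: str | Path) -> None:
    """Single-archive checkpoint: config JSON + weight arrays + seed."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "n_func": model.n_func,
        "seed": model.seed,
        "enc_config": asdict(model.enc_config),
        "fusion_config": asdict(model.fusion_config),
        "train_log": model.train_log,
    }
    arrays = {f"param/{k}": p.data for k, p in model.params.items()}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> BinderModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        model = BinderModel(meta["n_func"], EncoderConfig(**meta["enc_config"]),
                            FusionConfig(**meta["fusion_config"]), meta["seed"])
        model.train_log = meta["train_log"]
        for k in model.params:
            model.params[k] = ag.tensor(z[f"param/{k}"])
    return model


def write_scores_tsv(protein_id: str, mol_ids: Sequence[str],
                     probabilities: np.ndarray, path: str | Path) -> None:
    """Screening output: probability-descending, mol_id-ascending tiebreak."""
    order = sorted(range(len(mol_ids)),
                   key=lambda i: (-probabilities[i], mol_ids[i]))
    with open(path, "w") as fh:
        fh.write("protein_id\tmol_id\tprobability\trank\n")
        for rank, i in enumerate(order, start=1):
            fh.write(f"{protein_id}\t{mol_ids[i]}\t{probabilities[i]:.10f}\t{rank}\n")
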