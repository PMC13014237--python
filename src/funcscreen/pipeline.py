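"""End-to-end runs: reproducible pipeline stages and experiment recipes.

Each stage function mirrors one step a practitioner would run — simulate,
curate, split, train, screen, evaluate, filter-similar — reading and writing
the interchange formats defined by the other modules and dropping a
``RunManifest`` next to every output so any result can be traced back to its
inputs, configuration and seeds. The experiment recipes at the bottom wire
the stages into the screening-benchmark protocols used by the test-suite and
the acceptance script (planted-world learnability, decoy ablation, zero-shot
transfer).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from . import __version__
from .chem import (MolGraph, morgan_fingerprint, parse_smiles,
                   read_compound_table)
from .curation import (LabeledPair, label_activity_table, read_activity_csv,
                       read_labeled_pairs, sample_decoys,
                       scaffold_balanced_split, write_labeled_pairs,
                       write_split)
from .encoder import EncoderConfig
from .evaluation import (EvalReport, ScreenResult, enrichment_factor,
                         evaluate, filter_similar_pairs,
                         write_removed_pairs_tsv)
from .model import (BinderModel, EnsembleModel, FusionConfig, PairDataset,
                    TrainConfig, load_checkpoint, save_checkpoint, train,
                    train_ensemble, write_scores_tsv)
from .profunc import (ProteinFunctionVector, load_function_vectors, read_fasta,
                      attach_sequences)
from .synthdata import (SyntheticWorld, WorldSpec, WorldView, generate_world,
                        write_world_files, zero_shot_holdout)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# manifests and config files

def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict
    inputs: dict[str, str]
    seeds: dict[str, int]
    version: str = __version__
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        self.timestamp = datetime.now(timezone.utc).isoformat()
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _manifest(command: str, config: dict, inputs: Iterable[str | Path],
              seeds: dict[str, int], out: Path) -> None:
    m = RunManifest(command=command, config=config,
                    inputs={str(p): _digest(Path(p)) for p in inputs},
                    seeds=seeds)
    m.write(out.with_suffix(out.suffix + ".manifest.json"))


def load_config(path: str | Path, **overrides):
    """Read a YAML config with ``encoder``/``fusion``/``train`` sections.

    Keyword overrides (``encoder={...}`` etc.) take precedence over file
    values, mirroring flag-over-file behaviour.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for section, extra in overrides.items():
        raw.setdefault(section, {}).update(extra)
    return (EncoderConfig(**raw.get("encoder", {})),
            FusionConfig(**raw.get("fusion", {})),
            TrainConfig(**raw.get("train", {})))


# ---------------------------------------------------------------------------
# pipeline stages

def simulate(outdir: str | Path, spec: WorldSpec = WorldSpec()) -> SyntheticWorld:
    """Generate a synthetic world and emit its input files."""
    world = generate_world(spec)
    paths = write_world_files(world, outdir)
    _manifest("simulate", asdict(spec), [], {"seed": spec.seed},
              Path(outdir) / "world")
    logger.info("simulate: %d proteins, %d molecules, %d records",
                len(world.proteins), len(world.molecules), len(world.records))
    return world


def curate(activity_csv: str | Path, out_pairs: str | Path,
           cutoff_um: float = 50.0, decoy_ratio: float = 1.0,
           seed: int = 0) -> list[LabeledPair]:
    """Label an activity table and append sampled decoys."""
    records = read_activity_csv(activity_csv)
    pairs, ambiguous = label_activity_table(records, cutoff_um)
    actives = [p for p in pairs if p.label == "active"]
    measured = ([(p.protein_id, p.mol_id) for p in pairs]
                + [a for a in ambiguous])
    pool = sorted({r.mol_id for r in records})
    decoys = sample_decoys(actives, pool, measured, ratio=decoy_ratio, seed=seed)
    all_pairs = pairs + decoys
    write_labeled_pairs(all_pairs, out_pairs)
    _manifest("curate", {"cutoff_um": cutoff_um, "decoy_ratio": decoy_ratio,
                         "n_ambiguous": len(ambiguous),
                         "n_decoys": len(decoys)},
              [activity_csv], {"seed": seed}, Path(out_pairs))
    logger.info("curate: %d labeled, %d ambiguous excluded, %d decoys",
                len(pairs), len(ambiguous), len(decoys))
    return all_pairs


def split(compounds_csv: str | Path, out_split: str | Path,
          fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
          seed: int = 0):
    """Scaffold-balanced split of a compound table."""
    mols = read_compound_table(compounds_csv)
    assignment = scaffold_balanced_split(mols, fractions, seed)
    write_split(assignment, out_split)
    _manifest("split", {"fractions": fractions}, [compounds_csv],
              {"seed": seed}, Path(out_split))
    return assignment


def train_models(pairs_csv: str | Path, function_csv: str | Path,
                 compounds_csv: str | Path, out_dir: str | Path,
                 ensemble: int = 1,
                 enc: EncoderConfig = EncoderConfig(),
                 fusion: FusionConfig = FusionConfig(),
                 tc: TrainConfig = TrainConfig()) -> EnsembleModel:
    """Train one model or an ensemble from interchange files; save checkpoints."""
    dataset = PairDataset.from_labeled_pairs(
        read_labeled_pairs(pairs_csv),
        load_function_vectors(function_csv),
        read_compound_table(compounds_csv))
    model = train_ensemble(dataset, n_members=ensemble, fusion=fusion,
                           enc=enc, tc=tc)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, member in enumerate(model.members):
        save_checkpoint(member, out_dir / f"member_{i}.npz")
    _manifest("train", {"ensemble": ensemble, "encoder": asdict(enc),
                        "fusion": asdict(fusion), "train": asdict(tc)},
              [pairs_csv, function_csv, compounds_csv],
              {"seed": tc.seed, "split_seed": tc.split_seed},
              out_dir / "checkpoints")
    return model


def load_ensemble(checkpoint_dir: str | Path) -> EnsembleModel:
    paths = sorted(Path(checkpoint_dir).glob("member_*.npz"))
    members = [load_checkpoint(p) for p in paths]
    return EnsembleModel(members=members,
                         member_seeds=[m.seed for m in members])


def screen(models: BinderModel | EnsembleModel,
           protein: ProteinFunctionVector, library: Sequence[MolGraph],
           out_tsv: str | Path | None = None,
           labels: Sequence[int] | None = None) -> ScreenResult:
    """Rank a compound library against one protein."""
    probs = models.predict_probabilities(protein, list(library))
    result = ScreenResult.from_scores(protein.protein_id,
                                      [m.mol_id for m in library], probs, labels)
    if out_tsv is not None:
        write_scores_tsv(protein.protein_id, [m.mol_id for m in library],
                         probs, out_tsv)
        _manifest("screen", {"n_library": len(library)}, [],
                  {}, Path(out_tsv))
    return result


def evaluate_screen(result: ScreenResult, out_json: str | Path | None = None,
                    ef_fractions: Sequence[float] = (0.01, 0.05, 0.1),
                    thresholds: Sequence[float] = (0.45, 0.5)) -> EvalReport:
    report = evaluate(result, ef_fractions, thresholds,
                      metadata={"protein_id": result.protein_id,
                                "n": result.n})
    if out_json is not None:
        report.to_json(out_json)
        _manifest("evaluate", {"ef_fractions": list(ef_fractions),
                               "thresholds": list(thresholds)}, [], {},
                  Path(out_json))
    return report


def filter_similar(test_pairs, train_pairs, threshold, sequences, smiles,
                   out_tsv: str | Path | None = None, radius: int = 2,
                   n_bits: int = 2048, mode: str = "product"):
    """Leakage filter over interchange pair lists (computes fingerprints).

    ``smiles`` maps mol_id -> SMILES; canonicalisation and fingerprinting
    happen here.
    """
    graphs = {m: parse_smiles(s, m) for m, s in smiles.items()}
    fps = {m: morgan_fingerprint(g, radius, n_bits) for m, g in graphs.items()}
    retained, removed = filter_similar_pairs(
        test_pairs, train_pairs, threshold, sequences, fps,
        smiles={m: g.smiles for m, g in graphs.items()},
        mode=mode)
    if out_tsv is not None:
        write_removed_pairs_tsv(removed, out_tsv)
        _manifest("filter-similar", {"threshold": threshold, "mode": mode},
                  [], {}, Path(out_tsv))
    return retained, removed


# ---------------------------------------------------------------------------
# experiment recipes (desk-scale benchmark protocols)

DESK_ENCODER = EncoderConfig(hidden_dim=32, depth=2)
DESK_FUSION = FusionConfig(ffn_hidden=64, dropout=0.1)


def build_training_dataset(proteins: Sequence[ProteinFunctionVector],
                           molecules: Sequence[MolGraph],
                           records, cutoff_um: float = 50.0,
                           decoy_ratio: float = 1.0, seed: int = 0,
                           allowed_mols: set[str] | None = None) -> PairDataset:
    """Curate records into a training PairDataset (labels + decoys).

    ``allowed_mols`` restricts both measured pairs and the decoy pool to a
    molecule subset (the train partition of an outer split).
    """
    recs = [r for r in records
            if allowed_mols is None or r.mol_id in allowed_mols]
    pairs, ambiguous = label_activity_table(recs, cutoff_um)
    if decoy_ratio > 0:
        actives = [p for p in pairs if p.label == "active"]
        measured = [(p.protein_id, p.mol_id) for p in pairs] + ambiguous
        pool = sorted({r.mol_id for r in recs})
        pairs = pairs + sample_decoys(actives, pool, measured,
                                      ratio=decoy_ratio, seed=seed)
    return PairDataset.from_labeled_pairs(pairs, proteins, molecules)


def mean_heldout_ef(models: BinderModel | EnsembleModel,
                    proteins: Sequence[ProteinFunctionVector],
                    world: SyntheticWorld,
                    mol_ids: Sequence[str],
                    alpha: float = 0.01) -> float:
    """Mean EF over proteins, screening ``mol_ids`` with ground-truth labels.

    Proteins whose test library has no true binder (or only binders) are
    skipped: EF is undefined there.
    """
    graphs = [world.molecules[world.molecule_index[m]] for m in mol_ids]
    efs = []
    for prot in proteins:
        labels = [world.true_label(prot.protein_id, m) for m in mol_ids]
        if sum(labels) in (0, len(labels)):
            continue
        result = screen(models, prot, graphs, labels=labels)
        efs.append(enrichment_factor(result, alpha))
    if not efs:
        raise ValueError("no protein had a mixed-label test library")
    return float(np.mean(efs))


def run_learnability_experiment(seed: int, n_members: int = 3,
                                epochs: int = 15,
                                spec: WorldSpec | None = None,
                                decoy_ratio: float = 1.0,
                                test_fraction: float = 0.2) -> dict:
    """Train an ensemble on a planted world; report held-out mean EF1%.

    Protocol: generate the world, scaffold-split its molecules into a train
    pool and a held-out test set, curate training pairs (with decoys) from
    train-pool records only, train, then screen each protein over the held-out
    molecules against ground-truth binding labels.
    """
    spec = spec or WorldSpec(seed=seed)
    if spec.seed != seed:
        spec = dataclasses.replace(spec, seed=seed)
    world = generate_world(spec)
    outer = scaffold_balanced_split(world.molecules,
                                    (1.0 - test_fraction, 0.0, test_fraction),
                                    seed=seed)
    train_mols = set(outer.partition("train"))
    test_mols = outer.partition("test")
    dataset = build_training_dataset(world.proteins, world.molecules,
                                     world.records, decoy_ratio=decoy_ratio,
                                     seed=seed, allowed_mols=train_mols)
    tc = TrainConfig(epochs=epochs, batch_size=256, learning_rate=3e-3,
                     seed=seed, split_seed=seed)
    if n_members == 1:
        models: BinderModel | EnsembleModel = train(dataset, DESK_FUSION,
                                                    DESK_ENCODER, tc)
    else:
        models = train_ensemble(dataset, n_members=n_members,
                                fusion=DESK_FUSION, enc=DESK_ENCODER, tc=tc)
    ef = mean_heldout_ef(models, world.proteins, world, test_mols)
    return {"seed": seed, "ef1": ef, "n_test_molecules": len(test_mols),
            "n_train_pairs": len(dataset.pairs)}


def run_decoy_ablation(seed: int, epochs: int = 15) -> dict:
    """Paired decoy-free vs decoy-augmented runs on an imbalanced world.

    The world's measured records are biased 10:1 toward actives per protein
    (the scarce-negatives regime); both runs share the world, the split and
    all seeds, differing only in decoy augmentation (ratio 1 vs 0).
    """
    spec = WorldSpec(seed=seed, positive_record_fraction=10.0 / 11.0)
    world = generate_world(spec)
    outer = scaffold_balanced_split(world.molecules, (0.8, 0.0, 0.2), seed=seed)
    train_mols = set(outer.partition("train"))
    test_mols = outer.partition("test")
    tc = TrainConfig(epochs=epochs, batch_size=256, learning_rate=3e-3,
                     seed=seed, split_seed=seed)
    out = {"seed": seed}
    for tag, ratio in (("decoy_free", 0.0), ("decoy_augmented", 1.0)):
        dataset = build_training_dataset(world.proteins, world.molecules,
                                         world.records, decoy_ratio=ratio,
                                         seed=seed, allowed_mols=train_mols)
        model = train(dataset, DESK_FUSION, DESK_ENCODER, tc)
        out[tag] = mean_heldout_ef(model, world.proteins, world, test_mols)
    return out


def run_zero_shot_experiment(seed: int, held_proteins: int = 2,
                             epochs: int = 15) -> dict:
    """Zero-shot transfer: hold whole proteins (same archetype) out of training.

    All records of the held proteins move to the test side (zero training
    actives for them); the trained model then screens the full molecule
    library for each held protein against ground-truth binding labels.
    """
    world = generate_world(WorldSpec(seed=seed))
    train_view, test_view = zero_shot_holdout(world, held_proteins)
    dataset = build_training_dataset(train_view.proteins, world.molecules,
                                     train_view.records, seed=seed)
    tc = TrainConfig(epochs=epochs, batch_size=256, learning_rate=3e-3,
                     seed=seed, split_seed=seed)
    model = train(dataset, DESK_FUSION, DESK_ENCODER, tc)
    ef = mean_heldout_ef(model, test_view.proteins, world,
                         [m.mol_id for m in world.molecules])
    return {"seed": seed, "ef1": ef,
            "held_proteins": sorted(test_view.protein_ids)}
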