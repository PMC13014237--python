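"""Fusion, classification head, training loop, ensembling, checkpoints."""

import numpy as np
import pytest

from funcscreen.chem import parse_smiles
from funcscreen.curation import LabeledPair
from funcscreen.encoder import EncoderConfig
from funcscreen.model import (BinderModel, EnsembleModel, FusionConfig,
                              PairDataset, TrainConfig, ensemble_predict,
                              fuse, load_checkpoint, predict_pair,
                              save_checkpoint, train, train_ensemble,
                              write_scores_tsv)
from funcscreen.profunc import ProteinFunctionVector

ENC = EncoderConfig(hidden_dim=8, depth=1)
FUS = FusionConfig(ffn_layers=2, ffn_hidden=8, dropout=0.0)


def _protein(pid, scores):
    return ProteinFunctionVector(pid, np.asarray(scores, dtype=float))


def _toy_dataset(n_func=4):
    """Two proteins x two molecules, linearly separable planted labels."""
    prots = [_protein("P1", [1, 0, 0, 0]), _protein("P2", [0, 1, 0, 0])]
    mols = [parse_smiles("CCO", "M1"), parse_smiles("c1ccccc1", "M2")]
    labeled = [LabeledPair("P1", "M1", "active", "measured"),
               LabeledPair("P1", "M2", "inactive", "measured"),
               LabeledPair("P2", "M1", "inactive", "measured"),
               LabeledPair("P2", "M2", "active", "measured")]
    return PairDataset.from_labeled_pairs(labeled, prots, mols)


class TestFuse:
    def test_add_identity(self):
        h = np.array([1.0, -2.0, 3.0])
        assert np.array_equal(fuse(h, np.zeros(3), FusionConfig(mode="add")), h)

    def test_concat_preserves_blocks(self):
        out = fuse(np.arange(3.0), np.arange(4.0),
                   FusionConfig(mode="concat"))
        assert out.shape == (7,)
        assert np.array_equal(out[:3], np.arange(3.0))
        assert np.array_equal(out[3:], np.arange(4.0))

    def test_add_elementwise_sums(self):
        out = fuse(np.array([0.5, -1.0]), np.array([0.25, 2.0]),
                   FusionConfig(mode="add"))
        assert np.array_equal(out, [0.75, 1.0])

    def test_add_dim_mismatch(self):
        with pytest.raises(ValueError):
            fuse(np.zeros(3), np.zeros(4), FusionConfig(mode="add"))


class TestPredict:
    def test_zero_weights_give_half(self):
        model = BinderModel(4, ENC, FUS, seed=0)
        for p in model.params.values():
            p.data[...] = 0.0
        prob = predict_pair(_protein("P", [0.2, 0.8, 0.1, 0.0]),
                            parse_smiles("CCO", "M"), model)
        assert prob == 0.5

    def test_pinned_single_layer_head(self):
        """1-layer FFN with pinned weights: probability is a hand-computed sigmoid."""
        cfg = FusionConfig(ffn_layers=1, dropout=0.0)
        enc = EncoderConfig(hidden_dim=4, depth=0)
        model = BinderModel(2, enc, cfg, seed=0)
        g = parse_smiles("C", "M")
        # pin: encoder output = relu(W_o [x;0] + b_o); zero W_o -> b_o only
        model.params["enc.W_o"].data[...] = 0.0
        model.params["enc.b_o"].data[...] = [1.0, 0.0, 2.0, 0.0]
        model.params["proj.W"].data[...] = 0.0
        model.params["proj.b"].data[...] = [0.0, 1.0, 0.0, 0.0]
        model.params["ffn.W0"].data[...] = np.array([[1.0], [1.0], [-1.0], [0.0]])
        model.params["ffn.b0"].data[...] = 0.5
        # fused = [1,1,2,0]; logit = 1 + 1 - 2 + 0.5 = 0.5
        expect = 1.0 / (1.0 + np.exp(-0.5))
        prob = predict_pair(_protein("P", [0.0, 0.0]), g, model)
        assert np.isclose(prob, expect, atol=1e-12)

    def test_inference_deterministic_bitwise(self):
        model = BinderModel(4, ENC, FusionConfig(dropout=0.5), seed=3)
        prot = _protein("P", [0.1, 0.9, 0.3, 0.2])
        g = parse_smiles("CC(=O)NC", "M")
        assert predict_pair(prot, g, model) == predict_pair(prot, g, model)

    def test_n_func_mismatch(self):
        model = BinderModel(4, ENC, FUS, seed=0)
        with pytest.raises(ValueError):
            predict_pair(_protein("P", [0.1, 0.2]), parse_smiles("CC", "M"), model)


class TestTrain:
    def test_separable_data_converges(self):
        ds = _toy_dataset()
        tc = TrainConfig(epochs=200, batch_size=4, learning_rate=0.02,
                         seed=0, val_fraction=0.0)
        model = train(ds, FUS, ENC, tc)
        assert model.train_log["final_train_loss"] < 0.1

    def test_seeded_determinism(self):
        ds = _toy_dataset()
        tc = TrainConfig(epochs=10, batch_size=2, learning_rate=0.01,
                         seed=5, val_fraction=0.0)
        m1 = train(ds, FUS, ENC, tc)
        m2 = train(ds, FUS, ENC, tc)
        for k in m1.params:
            assert np.array_equal(m1.params[k].data, m2.params[k].data), k

    def test_label_flip_symmetry(self):
        """Training on flipped labels yields approximately mirrored predictions."""
        ds = _toy_dataset()
        flipped = PairDataset([(p, m, 1 - y) for p, m, y in ds.pairs],
                              ds.proteins, ds.molecules)
        tc = TrainConfig(epochs=300, batch_size=4, learning_rate=0.02,
                         seed=1, val_fraction=0.0)
        m_orig = train(ds, FUS, ENC, tc)
        m_flip = train(flipped, FUS, ENC, tc)
        for pid, mid, _ in ds.pairs:
            p0 = predict_pair(ds.proteins[pid], ds.molecules[mid], m_orig)
            p1 = predict_pair(ds.proteins[pid], ds.molecules[mid], m_flip)
            assert abs(p1 - (1.0 - p0)) < 0.2

    def test_single_class_raises(self):
        ds = _toy_dataset()
        ds.pairs = [(p, m, 1) for p, m, _ in ds.pairs]
        with pytest.raises(ValueError, match="both classes"):
            train(ds, FUS, ENC, TrainConfig(epochs=1, val_fraction=0.0))

    def test_decoys_count_as_negatives(self):
        """A decoy-labeled pair enters training with label 0, like an inactive."""
        prots = [_protein("P1", [1, 0, 0, 0])]
        mols = [parse_smiles("CCO", "M1"), parse_smiles("CCCC", "M2")]
        labeled = [LabeledPair("P1", "M1", "active", "measured"),
                   LabeledPair("P1", "M2", "decoy", "assumed_negative")]
        ds = PairDataset.from_labeled_pairs(labeled, prots, mols)
        assert sorted(y for _, _, y in ds.pairs) == [0, 1]


class TestEnsemble:
    def test_identical_members_equal_single(self):
        m = BinderModel(4, ENC, FUS, seed=0)
        ens = EnsembleModel([m, m, m], [0, 0, 0])
        prot, g = _protein("P", [0.5, 0.1, 0.2, 0.9]), parse_smiles("CCN", "M")
        assert ensemble_predict(ens, prot, g) == predict_pair(prot, g, m)

    def test_mean_of_pinned_members(self):
        """Members pinned to probabilities 0.2 / 0.4 / 0.6 average to 0.4."""
        members = []
        for target in (0.2, 0.4, 0.6):
            m = BinderModel(4, ENC, FusionConfig(ffn_layers=1, dropout=0.0), seed=0)
            for p in m.params.values():
                p.data[...] = 0.0
            m.params["ffn.b0"].data[...] = np.log(target / (1 - target))
            members.append(m)
        ens = EnsembleModel(members, [0, 1, 2])
        prob = ensemble_predict(ens, _protein("P", [0, 0, 0, 0]),
                                parse_smiles("C", "M"))
        assert np.isclose(prob, 0.4, atol=1e-12)

    def test_mean_matches_external_average(self, rng):
        members = [BinderModel(4, ENC, FUS, seed=s) for s in range(3)]
        ens = EnsembleModel(members, list(range(3)))
        mols = [parse_smiles(s, f"M{i}") for i, s in enumerate(
            ["CCO", "c1ccccc1", "CC(C)C", "CCNCC", "C1CCCCC1"])]
        for i in range(20):
            prot = _protein(f"P{i}", rng.uniform(size=4))
            g = mols[i % len(mols)]
            external = np.mean([predict_pair(prot, g, m) for m in members])
            assert abs(ensemble_predict(ens, prot, g) - external) < 1e-12

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            EnsembleModel([], [])


class TestCheckpointAndScores:
    def test_checkpoint_roundtrip(self, tmp_path):
        ds = _toy_dataset()
        tc = TrainConfig(epochs=5, batch_size=2, seed=2, val_fraction=0.0)
        model = train(ds, FUS, ENC, tc)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        prot, g = ds.proteins["P1"], ds.molecules["M1"]
        assert predict_pair(prot, g, back) == predict_pair(prot, g, model)
        assert back.seed == model.seed
        assert back.train_log["n_train_pairs"] == 4

    def test_scores_tsv_ordering(self, tmp_path):
        path = tmp_path / "scores.tsv"
        write_scores_tsv("P1", ["m_b", "m_a", "m_c"],
                         np.array([0.5, 0.9, 0.5]), path)
        lines = path.read_text().strip().split("\n")
        rows = [l.split("\t") for l in lines[1:]]
        assert [r[1] for r in rows] == ["m_a", "m_b", "m_c"]  # tie: mol_id asc
        assert [r[3] for r in rows] == ["1", "2", "3"]

    def test_ensemble_split_seeds_distinct(self):
        ds = _toy_dataset()
        tc = TrainConfig(epochs=2, batch_size=4, seed=0, split_seed=10,
                         val_fraction=0.0)
        ens = train_ensemble(ds, n_members=3, fusion=FUS, enc=ENC, tc=tc)
        assert ens.member_seeds == [10, 11, 12]
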