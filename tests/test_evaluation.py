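"""Enrichment factor, threshold confusion, global identity, leakage filter."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from funcscreen.chem import morgan_fingerprint, parse_smiles
from funcscreen.evaluation import (ScreenResult, confusion_at_threshold,
                                   enrichment_factor, evaluate,
                                   filter_similar_pairs, global_identity)


def make_result(n, active_ranks, probs=None, pid="P"):
    """Ranked result with actives at the given (1-based) ranks."""
    labels = [1 if r + 1 in active_ranks else 0 for r in range(n)]
    if probs is None:
        probs = np.linspace(1.0, 0.0, n)  # already sorted
    return ScreenResult.from_scores(pid, [f"m{r:05d}" for r in range(n)],
                                    probs, labels)


class TestEnrichmentFactor:
    def test_perfect_ranking(self):
        res = make_result(1000, set(range(1, 11)))
        assert enrichment_factor(res, 0.01) == pytest.approx(100.0)

    def test_bruteforce_example(self):
        # N=200, actives at ranks 1, 3, 150; alpha=0.05 -> top 10 holds 2
        res = make_result(200, {1, 3, 150})
        assert enrichment_factor(res, 0.05) == pytest.approx(2 / (0.05 * 3))

    def test_alpha_one_is_exactly_one(self, rng):
        for _ in range(10):
            labels = rng.integers(0, 2, size=50)
            if labels.sum() == 0:
                labels[0] = 1
            res = ScreenResult.from_scores("P", [f"m{i}" for i in range(50)],
                                           rng.uniform(size=50), labels)
            assert enrichment_factor(res, 1.0) == 1.0

    def test_monotone_rescaling_invariance(self, rng):
        probs = rng.uniform(size=300)
        labels = (rng.uniform(size=300) < 0.1).astype(int)
        labels[0] = 1
        ids = [f"m{i}" for i in range(300)]
        a = ScreenResult.from_scores("P", ids, probs, labels)
        b = ScreenResult.from_scores("P", ids, np.tanh(3 * probs), labels)
        for alpha in (0.01, 0.05, 0.2):
            assert enrichment_factor(a, alpha) == enrichment_factor(b, alpha)

    def test_random_baseline_small(self, rng):
        """Mean EF over shuffles approaches 1 (random ranking baseline)."""
        efs = []
        for _ in range(2000):
            labels = np.zeros(200, dtype=int)
            labels[rng.choice(200, size=20, replace=False)] = 1
            res = ScreenResult(protein_id="P",
                               mol_ids=tuple(f"m{i}" for i in range(200)),
                               probabilities=np.linspace(1, 0, 200),
                               labels=labels)
            efs.append(enrichment_factor(res, 0.05))
        se = np.std(efs) / math.sqrt(len(efs))
        assert abs(np.mean(efs) - 1.0) < 3 * se + 1e-9

    def test_no_actives_raises(self):
        res = ScreenResult.from_scores("P", ["a", "b"], [0.5, 0.2], [0, 0])
        with pytest.raises(ValueError, match="EF undefined"):
            enrichment_factor(res, 0.01)
        with pytest.raises(ValueError):
            enrichment_factor(make_result(10, {1}), 0.0)


class TestConfusion:
    def test_degenerate_thresholds(self):
        res = make_result(20, {1, 5, 9})
        c0 = confusion_at_threshold(res, 0.0)
        assert (c0.tp, c0.fp, c0.tn, c0.fn) == (3, 17, 0, 0)
        chigh = confusion_at_threshold(res, 1.1)
        assert (chigh.tp, chigh.fp) == (0, 0)
        assert chigh.precision is None

    def test_six_item_fixture_hand_counts(self):
        probs = [0.9, 0.8, 0.6, 0.4, 0.3, 0.1]
        labels = [1, 0, 1, 1, 0, 0]
        res = ScreenResult.from_scores("P", list("abcdef"), probs, labels)
        c = confusion_at_threshold(res, 0.5)
        # predicted positive: 0.9, 0.8, 0.6 -> labels 1, 0, 1
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 2, 1)
        assert c.precision == pytest.approx(2 / 3)
        assert c.recall == pytest.approx(2 / 3)
        assert c.f1 == pytest.approx(2 * (2 / 3) * (2 / 3) / (4 / 3))

    def test_counts_sum_and_f1_identity(self, rng):
        probs = rng.uniform(size=100)
        labels = (rng.uniform(size=100) < 0.3).astype(int)
        res = ScreenResult.from_scores("P", [f"m{i}" for i in range(100)],
                                       probs, labels)
        for tau in np.linspace(0, 1, 11):
            c = confusion_at_threshold(res, tau)
            assert c.tp + c.fp + c.tn + c.fn == 100
            if c.precision is not None and c.precision + c.recall > 0:
                assert c.f1 == pytest.approx(
                    2 * c.precision * c.recall / (c.precision + c.recall))

    def test_report_serialises(self, tmp_path):
        res = make_result(50, {1, 2, 30})
        report = evaluate(res, ef_fractions=(0.1,), thresholds=(0.5,))
        text = report.to_json(tmp_path / "r.json")
        assert '"ef"' in text and (tmp_path / "r.json").exists()


# --- independent affine-gap global alignment oracle -------------------------

def _gotoh_identity_set(a, b, open_=10.0, ext=0.5):
    """All-optimal-alignment identities under NW/BLOSUM62 with gap cost
    open + (L-1)*ext, via explicit three-state DP with full backtracking."""
    mat = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -open_ - (i - 1) * ext
    for j in range(1, m + 1):
        Iy[0][j] = -open_ - (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i-1][j-1], Ix[i-1][j-1], Iy[i-1][j-1]) + s
            Ix[i][j] = max(M[i-1][j] - open_, Ix[i-1][j] - ext,
                           Iy[i-1][j] - open_)
            Iy[i][j] = max(M[i][j-1] - open_, Ix[i][j-1] - open_,
                           Iy[i][j-1] - ext)
    best = max(M[n][m], Ix[n][m], Iy[n][m])
    idents = set()

    def walk(i, j, state, matches, length):
        if i == 0 and j == 0 and state == "M":
            idents.add(matches / length)
            return
        tol = 1e-9
        if state == "M":
            if i > 0 and j > 0:
                s = mat[a[i - 1], b[j - 1]]
                inc = (1 if a[i - 1] == b[j - 1] else 0, 1)
                for prev in ("M", "Ix", "Iy"):
                    val = {"M": M, "Ix": Ix, "Iy": Iy}[prev][i-1][j-1]
                    if abs(val + s - M[i][j]) < tol:
                        walk(i - 1, j - 1, prev if (i-1, j-1) != (0, 0) or prev == "M" else prev,
                             matches + inc[0], length + inc[1])
        elif state == "Ix":
            if i > 0:
                for prev, cost in (("M", open_), ("Ix", ext), ("Iy", open_)):
                    val = {"M": M, "Ix": Ix, "Iy": Iy}[prev][i-1][j]
                    if abs(val - cost - Ix[i][j]) < tol:
                        walk(i - 1, j, prev, matches, length + 1)
        else:
            if j > 0:
                for prev, cost in (("M", open_), ("Ix", open_), ("Iy", ext)):
                    val = {"M": M, "Ix": Ix, "Iy": Iy}[prev][i][j-1]
                    if abs(val - cost - Iy[i][j]) < tol:
                        walk(i, j - 1, prev, matches, length + 1)

    for state, val in (("M", M[n][m]), ("Ix", Ix[n][m]), ("Iy", Iy[n][m])):
        if abs(val - best) < 1e-9:
            walk(n, m, state, 0, 0)
    return best, idents


class TestGlobalIdentity:
    def test_identical_sequences(self):
        assert global_identity("MKVLLA", "MKVLLA") == 1.0

    def test_no_identical_positions(self):
        assert global_identity("AAAA", "CCCC") == 0.0

    def test_textbook_pair_matches_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        score, idents = _gotoh_identity_set(a, b)
        assert global_identity(a, b) in [pytest.approx(v) for v in idents]

    @pytest.mark.parametrize("pair", [("MKWVTF", "MKWTF"), ("ACDEFGH", "ACDFGH"),
                                      ("WWKLNP", "WWKQNP")])
    def test_random_pairs_match_dp_oracle(self, pair):
        score, idents = _gotoh_identity_set(*pair)
        assert global_identity(*pair) in [pytest.approx(v) for v in idents]

    def test_x_never_counts_identical(self):
        assert global_identity("AXA", "AXA") == pytest.approx(2 / 3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            global_identity("", "ACD")
        with pytest.raises(ValueError):
            global_identity("AC1D", "ACD")


# --- leakage filter ---------------------------------------------------------

def _entities(rng, n_prot, n_mol, tag):
    from funcscreen.synthdata import AMINO_ACIDS, FRAGMENT_LIBRARY
    base = "".join(rng.choice(list(AMINO_ACIDS), size=40))
    seqs = {}
    for i in range(n_prot):
        seq = list(base)
        for pos in range(len(seq)):
            if rng.random() < rng.uniform(0.05, 0.8):
                seq[pos] = AMINO_ACIDS[int(rng.integers(20))]
        seqs[f"{tag}P{i}"] = "".join(seq)
    fps, smiles = {}, {}
    for i in range(n_mol):
        k = int(rng.integers(2, 5))
        smi = "".join(FRAGMENT_LIBRARY[int(rng.integers(len(FRAGMENT_LIBRARY)))]
                      for _ in range(k))
        g = parse_smiles(smi, f"{tag}M{i}")
        fps[f"{tag}M{i}"] = morgan_fingerprint(g)
        smiles[f"{tag}M{i}"] = g.smiles
    return seqs, fps, smiles


class TestFilterSimilarPairs:
    def _fixture(self, rng, n_test=10, n_train=20):
        seqs_a, fps_a, smi_a = _entities(rng, 4, 5, "a")
        seqs_b, fps_b, smi_b = _entities(rng, 4, 6, "b")
        seqs = {**seqs_a, **seqs_b}
        fps = {**fps_a, **fps_b}
        smiles = {**smi_a, **smi_b}
        tp = sorted(seqs_a)
        tm = sorted(fps_a)
        trp = sorted(seqs_b)
        trm = sorted(fps_b)
        test_pairs = [(tp[rng.integers(len(tp))], tm[rng.integers(len(tm))])
                      for _ in range(n_test)]
        train_pairs = [(trp[rng.integers(len(trp))], trm[rng.integers(len(trm))])
                       for _ in range(n_train)]
        return test_pairs, train_pairs, seqs, fps, smiles

    def test_threshold_one_removes_nothing_without_duplicates(self, rng):
        test_pairs, train_pairs, seqs, fps, _ = self._fixture(rng)
        retained, removed = filter_similar_pairs(test_pairs, train_pairs, 1.0,
                                                 seqs, fps)
        assert removed == [] and retained == test_pairs

    def test_identical_pair_always_removed(self, rng):
        seqs, fps, smiles = _entities(rng, 2, 3, "s")
        pair = [("sP0", "sM0")]
        for thr in (0.9, 0.7, 0.5):
            retained, removed = filter_similar_pairs(pair, pair, thr, seqs, fps)
            assert retained == [] and len(removed) == 1
            assert removed[0].score == pytest.approx(1.0)
        retained, removed = filter_similar_pairs(pair, pair, 1.0, seqs, fps,
                                                 smiles=smiles, mode="exact")
        assert retained == []

    def test_matches_bruteforce_double_loop(self, rng):
        from funcscreen.chem import tanimoto
        for trial in range(3):
            test_pairs, train_pairs, seqs, fps, _ = self._fixture(rng)
            for thr in (0.9, 0.7, 0.5):
                retained, removed = filter_similar_pairs(
                    test_pairs, train_pairs, thr, seqs, fps)
                expect_removed = []
                for (p, m) in test_pairs:
                    hit = any(global_identity(seqs[p], seqs[q])
                              * tanimoto(fps[m], fps[r]) > thr
                              for q, r in train_pairs)
                    if hit:
                        expect_removed.append((p, m))
                assert [r.test_pair for r in removed] == expect_removed

    def test_removal_monotone_in_threshold(self, rng):
        test_pairs, train_pairs, seqs, fps, _ = self._fixture(rng, 20, 30)
        counts = []
        for thr in (0.9, 0.7, 0.5):
            _, removed = filter_similar_pairs(test_pairs, train_pairs, thr,
                                              seqs, fps)
            counts.append(len(removed))
        assert counts == sorted(counts)

    def test_missing_entities_named(self, rng):
        seqs, fps, _ = _entities(rng, 1, 1, "z")
        with pytest.raises(KeyError, match="ghost"):
            filter_similar_pairs([("ghost", "zM0")], [("zP0", "zM0")], 0.5,
                                 seqs, fps)
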