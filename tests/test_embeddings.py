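"""Sentence preprocessing, SGNS training, cosine scoring, vector arithmetic."""

import numpy as np
import pytest

from toxlitscore import (
    EmbeddingSpace,
    TrainingConfig,
    cosine_similarity,
    preprocess_sentences,
    toxicity_arithmetic_report,
    train_embeddings,
)

ENTITY_MAP = {
    "carbon tetrachloride": "D002251",
    "hepatotoxicity": "D056486",
}
ENTITY_TYPES = {"D002251": "chemical", "D056486": "disease"}


class TestPreprocess:
    def test_multiword_entity_normalized_to_single_token(self):
        out = preprocess_sentences(
            ["Carbon Tetrachloride induces HEPATOTOXICITY."], ENTITY_MAP, ENTITY_TYPES
        )
        assert out == [["D002251", "induces", "D056486"]]

    def test_single_entity_sentence_dropped(self):
        out = preprocess_sentences(
            ["Carbon Tetrachloride is a solvent."], ENTITY_MAP, ENTITY_TYPES
        )
        assert out == []

    def test_zero_entity_sentence_dropped(self):
        out = preprocess_sentences(["nothing to see here."], ENTITY_MAP, ENTITY_TYPES)
        assert out == []

    def test_noisy_tokens_removed(self):
        out = preprocess_sentences(
            ["carbon tetrachloride ... ## & x hepatotoxicity !!"],
            ENTITY_MAP,
            ENTITY_TYPES,
        )
        assert out == [["D002251", "D056486"]]

    def test_idempotent(self):
        once = preprocess_sentences(
            ["Carbon Tetrachloride induces Hepatotoxicity badly."],
            ENTITY_MAP,
            ENTITY_TYPES,
        )
        twice = preprocess_sentences(once, ENTITY_MAP, ENTITY_TYPES)
        assert twice == once

    def test_longest_match_wins_over_substring(self):
        emap = {"carbon": "D999999", **ENTITY_MAP}
        etypes = {"D999999": "chemical", **ENTITY_TYPES}
        out = preprocess_sentences(
            ["carbon tetrachloride causes hepatotoxicity"], emap, etypes
        )
        assert out[0][0] == "D002251"


def _topic_corpus(n=300, seed=0):
    """tokA/tokB share a topic vocabulary; tokC lives in another topic."""
    rng = np.random.default_rng(seed)
    sents = []
    for _ in range(n):
        sents.append(["tokA", "tokB", f"t{rng.integers(8)}", f"t{rng.integers(8)}"])
        sents.append(["tokC", f"u{rng.integers(8)}", f"u{rng.integers(8)}"])
    return sents


class TestTraining:
    def test_planted_structure_recovered(self):
        """Co-trained tokens end up closer than cross-topic tokens (5 seeds)."""
        sents = _topic_corpus()
        cfg = TrainingConfig(dimension=64, epochs=5, min_word_count=2, window=3)
        margin = []
        for seed in range(5):
            sp = train_embeddings(sents, cfg, seed=seed)
            margin.append(
                cosine_similarity(sp, "tokA", "tokB")
                - cosine_similarity(sp, "tokA", "tokC")
            )
        assert np.mean(margin) > 0.05

    def test_min_word_count_prunes(self):
        sents = [["common", "words", "here"]] * 5 + [["rare", "words", "here"]] * 4
        cfg = TrainingConfig(dimension=8, epochs=1, min_word_count=5, window=2)
        sp = train_embeddings(sents, cfg, seed=0)
        assert "rare" not in sp and "common" in sp

    def test_seed_determinism(self):
        sents = _topic_corpus(50)
        cfg = TrainingConfig(dimension=16, epochs=2, min_word_count=2, window=2)
        a = train_embeddings(sents, cfg, seed=3)
        b = train_embeddings(sents, cfg, seed=3)
        assert a.vocabulary == b.vocabulary
        assert np.array_equal(a.vectors, b.vectors)

    def test_output_vectors_unit_norm(self):
        sp = train_embeddings(
            _topic_corpus(50),
            TrainingConfig(dimension=16, epochs=1, min_word_count=2, window=2),
            seed=0,
        )
        assert sp.normalized
        norms = np.linalg.norm(sp.vectors, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)

    def test_empty_vocabulary_errors(self):
        with pytest.raises(ValueError):
            train_embeddings(
                [["one", "two"]],
                TrainingConfig(dimension=8, epochs=1, min_word_count=5),
                seed=0,
            )

    def test_save_load_round_trip(self, tmp_path):
        sp = train_embeddings(
            _topic_corpus(30),
            TrainingConfig(dimension=8, epochs=1, min_word_count=2, window=2),
            seed=1,
        )
        path = tmp_path / "vecs.txt"
        sp.save(path)
        loaded = EmbeddingSpace.load(path)
        assert loaded.vocabulary == sp.vocabulary
        assert np.allclose(loaded.vectors, sp.vectors, atol=1e-7)


class TestCosine:
    def _fixed_space(self):
        import math

        vecs = np.array(
            [[1.0, 0.0], [0.0, 1.0], [1 / math.sqrt(2), 1 / math.sqrt(2)]]
        )
        return EmbeddingSpace({"x": 0, "y": 1, "d": 2}, vecs, normalized=True)

    def test_identity(self):
        sp = self._fixed_space()
        assert cosine_similarity(sp, "x", "x") == pytest.approx(1.0)

    def test_orthogonal(self):
        sp = self._fixed_space()
        assert cosine_similarity(sp, "x", "y") == pytest.approx(0.0)

    def test_diagonal_hand_value(self):
        sp = self._fixed_space()
        assert cosine_similarity(sp, "d", "x") == pytest.approx(np.sqrt(2) / 2, abs=1e-9)

    def test_symmetry_and_bounds(self):
        sp = self._fixed_space()
        for a in sp.vocabulary:
            for b in sp.vocabulary:
                v = cosine_similarity(sp, a, b)
                assert -1.0 - 1e-9 <= v <= 1.0 + 1e-9
                assert v == pytest.approx(cosine_similarity(sp, b, a), abs=1e-12)

    def test_missing_token_is_lookup_error(self):
        with pytest.raises(KeyError):
            cosine_similarity(self._fixed_space(), "x", "absent")


class TestArithmeticReport:
    def _constructed_space(self, dim=16, n_pairs=4, seed=0):
        """Each toxicity vector is its organ vector plus a fixed offset."""
        rng = np.random.default_rng(seed)
        offset = rng.standard_normal(dim)
        vocab = {"toxicity": 0}
        rows = [offset]
        pairs = []
        for i in range(n_pairs):
            organ = rng.standard_normal(dim)
            vocab[f"organ{i}"] = len(rows)
            rows.append(organ)
            vocab[f"tox{i}"] = len(rows)
            rows.append(organ + offset)
            pairs.append((f"tox{i}", f"organ{i}"))
        return EmbeddingSpace(vocab, np.array(rows)), pairs

    def test_constructed_offset_gives_unit_cosine(self):
        sp, pairs = self._constructed_space()
        rep = toxicity_arithmetic_report(sp, pairs, "toxicity")
        assert rep.mean_cosine == pytest.approx(1.0, abs=1e-9)
        assert all(c == pytest.approx(1.0, abs=1e-9) for c in rep.pair_cosines.values())

    def test_single_pair_mean_is_that_difference(self):
        sp, pairs = self._constructed_space(n_pairs=1)
        rep = toxicity_arithmetic_report(sp, pairs[:1], "toxicity")
        want = sp.vector("tox0") - sp.vector("organ0")
        assert np.allclose(rep.mean_difference, want)

    def test_random_directions_nearly_orthogonal(self):
        """In high dimension, unrelated mean differences have small cosine."""
        dim = 1000
        cosines = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vocab = {"toxicity": 0, "a": 1, "b": 2}
            vecs = rng.standard_normal((3, dim))
            sp = EmbeddingSpace(vocab, vecs)
            rep = toxicity_arithmetic_report(sp, [("a", "b")], "toxicity")
            cosines.append(abs(rep.mean_cosine))
        assert np.mean(cosines) < 0.2

    def test_missing_tokens_listed_as_skipped(self):
        sp, pairs = self._constructed_space()
        rep = toxicity_arithmetic_report(
            sp, pairs + [("ghost", "organ0")], "toxicity"
        )
        assert ("ghost", "organ0") in rep.skipped

    def test_pca_coords_cover_all_tokens(self):
        sp, pairs = self._constructed_space()
        rep = toxicity_arithmetic_report(sp, pairs, "toxicity")
        assert set(rep.pca_coords) == {"toxicity"} | {t for p in pairs for t in p}
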