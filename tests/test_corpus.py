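"""Lexicon generation: overlap constraints, distances, validation."""

import json

import numpy as np
import pytest

from lexhub.corpus import (
    Corpus,
    CorpusConfig,
    GenerationError,
    SET_ROLES,
    assemble_corpus,
    cosine_distance,
    distance_summary,
    generate_phonological_form,
    make_onset_competitor,
    make_rhyme_competitor,
    make_semantic_neighbor,
    make_visual_competitor,
    sample_phoneme_inventory,
    validate_corpus,
    _SemanticPool,
)

SMALL = CorpusConfig(n_sets=5, n_fillers=8)


class TestCosineDistance:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ([1, 0, 1, 1], [1, 0, 1, 1], 0.0),  # identity
            ([1, 1, 0, 0], [0, 0, 1, 1], 1.0),  # disjoint supports
        ],
    )
    def test_extremes(self, u, v, expected):
        assert cosine_distance(u, v) == pytest.approx(expected)

    def test_half_shared_8_feature_sets(self):
        # 4 of 8 shared active features -> distance exactly 0.5
        u = np.zeros(200)
        v = np.zeros(200)
        u[:8] = 1
        v[4:12] = 1
        assert cosine_distance(u, v) == pytest.approx(0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance([0, 0], [1, 0])


class TestPhonemeInventory:
    def test_shape_and_determinism(self):
        inv1 = sample_phoneme_inventory(42)
        inv2 = sample_phoneme_inventory(42)
        assert inv1.features.shape == (20, 10)
        assert np.array_equal(inv1.features, inv2.features)
        assert len({tuple(r) for r in inv1.features}) == 20

    def test_bit_activation_rate(self):
        # pooled over many inventories the activation rate is ~0.5
        total = sum(
            sample_phoneme_inventory(s).features.sum() for s in range(200)
        )
        n = 200 * 20 * 10
        # 5 sigma band of Binomial(n, 0.5); distinctness rejection barely biases it
        assert abs(total - n / 2) < 5 * np.sqrt(n * 0.25)


class TestPhonologicalForms:
    cfg = SMALL

    def test_word_legal_under_empty_constraints(self):
        rng = np.random.default_rng(0)
        empty = np.empty((0, 6), dtype=np.int64)
        w = generate_phonological_form(self.cfg, empty, rng)
        assert len(w) == 6
        assert np.bincount(np.array(w)).max() <= 2

    def test_triple_repeat_rejected(self):
        # a fixed triple repeat is impossible to complete legally
        rng = np.random.default_rng(0)
        empty = np.empty((0, 6), dtype=np.int64)
        with pytest.raises(GenerationError):
            generate_phonological_form(
                self.cfg, empty, rng, fixed={0: 3, 1: 3, 2: 3}
            )

    def test_three_consecutive_overlap_rejected(self):
        rng = np.random.default_rng(1)
        accepted = np.array([[1, 2, 3, 4, 5, 6]])
        # force the first three slots to match the accepted word
        with pytest.raises(GenerationError):
            generate_phonological_form(
                self.cfg, accepted, rng, fixed={0: 1, 1: 2, 2: 3}
            )

    def test_onset_competitor_structure(self):
        rng = np.random.default_rng(2)
        target = (1, 2, 3, 4, 5, 6)
        empty = np.empty((0, 6), dtype=np.int64)
        for _ in range(20):
            comp = make_onset_competitor(target, self.cfg, empty, rng)
            assert comp[:3] == target[:3]
            assert comp[3] != target[3]

    def test_rhyme_competitor_structure(self):
        rng = np.random.default_rng(3)
        target = (1, 2, 3, 4, 5, 6)
        empty = np.empty((0, 6), dtype=np.int64)
        for _ in range(20):
            comp = make_rhyme_competitor(target, self.cfg, empty, rng)
            assert comp[3:] == target[3:]
            assert comp[2] != target[2]


class TestVisualCompetitor:
    def test_minimum_agreement(self):
        cfg = SMALL
        rng = np.random.default_rng(4)
        target = rng.integers(0, 2, 20).astype(np.int8)
        for _ in range(50):
            comp = make_visual_competitor(target, cfg, rng)
            assert (comp == target).sum() >= 10

    def test_all_zero_target_copies_zeros(self):
        cfg = SMALL
        rng = np.random.default_rng(5)
        comp = make_visual_competitor(np.zeros(20, dtype=np.int8), cfg, rng)
        # at least the 10 copied positions are zero
        assert (comp == 0).sum() >= 10


class TestSemanticNeighbors:
    @pytest.mark.parametrize("n_shared,expected", [(4, 0.5), (2, 0.75)])
    def test_exact_distances(self, n_shared, expected):
        cfg = SMALL
        rng = np.random.default_rng(6)
        pool = _SemanticPool(cfg.sem_features, rng)
        target = pool.sample(cfg.sem_active)
        t_idx = pool.add(target)
        neigh = make_semantic_neighbor(target, n_shared, pool, cfg, rng, t_idx)
        assert len(neigh & target) == n_shared
        u = np.zeros(200)
        v = np.zeros(200)
        u[list(target)] = 1
        v[list(neigh)] = 1
        assert cosine_distance(u, v) == pytest.approx(1 - n_shared / 8)

    def test_degenerate_full_share_is_identity(self):
        cfg = SMALL
        rng = np.random.default_rng(7)
        pool = _SemanticPool(cfg.sem_features, rng)
        target = pool.sample(cfg.sem_active)
        t_idx = pool.add(target)
        neigh = make_semantic_neighbor(target, 8, pool, cfg, rng, t_idx)
        assert neigh == target


class TestAssembleAndValidate:
    def test_small_corpus_structure(self, small_corpus):
        cfg = small_corpus.config
        assert len(small_corpus) == cfg.n_items
        assert len(small_corpus.target_sets) == cfg.n_sets
        for ts in small_corpus.target_sets:
            assert set(ts) == set(SET_ROLES)
        assert len(small_corpus.fillers) == cfg.n_fillers

    def test_fresh_corpus_passes_validation(self, small_corpus):
        report = validate_corpus(small_corpus)
        assert report.ok, report.summary()

    def test_different_seeds_differ(self):
        c1 = assemble_corpus(SMALL, seed=1)
        c2 = assemble_corpus(SMALL, seed=2)
        assert not np.array_equal(c1.words(), c2.words())
        assert validate_corpus(c1).ok and validate_corpus(c2).ok

    def test_same_seed_reproduces(self):
        c1 = assemble_corpus(SMALL, seed=9)
        c2 = assemble_corpus(SMALL, seed=9)
        assert np.array_equal(c1.words(), c2.words())
        assert np.array_equal(c1.semantic_matrix(), c2.semantic_matrix())
        assert np.array_equal(c1.visual_matrix(), c2.visual_matrix())

    def test_injected_semantic_fault_is_flagged(self, small_corpus):
        # mutate the near neighbor of set 0 to share 5 features with its target
        import dataclasses

        corpus = Corpus(
            items=list(small_corpus.items),
            inventory=small_corpus.inventory,
            target_sets=small_corpus.target_sets,
            seed=small_corpus.seed,
            config=small_corpus.config,
        )
        ts = corpus.target_sets[0]
        target = corpus.item(ts["target"])
        near = corpus.item(ts["near_sem"])
        extra = sorted(target.semantics - near.semantics)[0]
        dropped = sorted(near.semantics - target.semantics)[0]
        mutated = frozenset((near.semantics - {dropped}) | {extra})
        corpus.items[near.id] = dataclasses.replace(near, semantics=mutated)
        report = validate_corpus(corpus)
        assert not report.ok
        assert any("near_sem" in rule for rule, _ in report.violations)

    def test_unrelated_phonology_brute_force(self, small_corpus):
        # pairwise scan: no first-4/final-4 sharing, no 3-consecutive overlap
        words = small_corpus.words()
        related = set()
        for ts in small_corpus.target_sets:
            related.add(frozenset((ts["target"], ts["onset_comp"])))
            related.add(frozenset((ts["target"], ts["rhyme_comp"])))
        n = len(words)
        for i in range(n):
            for j in range(i + 1, n):
                assert not np.array_equal(words[i][:4], words[j][:4])
                assert not np.array_equal(words[i][-4:], words[j][-4:])
                if frozenset((i, j)) in related:
                    continue
                for s in range(4):
                    assert not np.array_equal(
                        words[i][s : s + 3], words[j][s : s + 3]
                    ), f"items {i},{j} share 3 consecutive phonemes"


class TestDistanceSummary:
    def test_exact_semantic_rows(self, small_corpus):
        df = distance_summary([small_corpus])
        assert df.loc["near_sem", "mean"] == pytest.approx(0.5)
        assert df.loc["near_sem", "std"] == pytest.approx(0.0)
        assert df.loc["far_sem", "mean"] == pytest.approx(0.75)
        assert df.loc["far_sem", "std"] == pytest.approx(0.0)

    def test_all_relations_present_and_bounded(self, small_corpus):
        df = distance_summary([small_corpus])
        assert ((df["mean"] >= 0) & (df["mean"] <= 1)).all()
        assert (df["n_pairs"] > 0).all()

    def test_requires_input(self):
        with pytest.raises(ValueError):
            distance_summary([])


class TestSerialization:
    def test_json_round_trip(self, small_corpus, tmp_path):
        path = tmp_path / "corpus.json"
        small_corpus.to_json(path)
        back = Corpus.from_json(path)
        assert np.array_equal(back.words(), small_corpus.words())
        assert np.array_equal(back.semantic_matrix(), small_corpus.semantic_matrix())
        assert np.array_equal(back.visual_matrix(), small_corpus.visual_matrix())
        assert back.target_sets == small_corpus.target_sets
        assert [it.role for it in back.items] == [it.role for it in small_corpus.items]

    def test_csv_export(self, small_corpus, tmp_path):
        import pandas as pd

        path = tmp_path / "corpus.csv"
        small_corpus.to_csv(path)
        df = pd.read_csv(path)
        assert len(df) == len(small_corpus)
        assert set(df.columns) >= {"id", "role", "set_id", "phonemes", "visual", "semantics"}
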