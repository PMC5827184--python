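"""Evaluation: perplexity, the balanced-accuracy sweep, clustering, PCA."""

import numpy as np
import pytest

from semlearn.corpus import InvalidConfigError
from semlearn.evaluation import (
    ThresholdGrid,
    balanced_accuracy_sweep,
    category_similarity_matrix,
    hierarchical_cluster,
    nearest_neighbors,
    pca_loadings,
    perplexity,
)
from semlearn.networks import InitSpec, SRNWeights, init_weights
from semlearn.semspace import ProbeSet, RepresentationMatrix, SimilarityMatrix

from .conftest import brute_force_sweep


def _sim(values, words):
    return SimilarityMatrix(values=np.asarray(values, dtype=float),
                            row_words=list(words), col_words=list(words))


class TestPerplexity:
    def test_near_perfect_predictor_scores_one(self):
        w = init_weights(InitSpec(seed=0), "srn", 8, 4)
        w.w_out[:] = 0.0
        w.b_out[:] = -200.0
        w.b_out[3] = 200.0
        tokens = np.full(50, 3)
        assert perplexity(w, tokens, pad_id=0) == pytest.approx(1.0)

    def test_uniform_over_fifty_scores_fifty(self):
        w = SRNWeights(np.zeros((50, 4)), np.zeros((4, 4)),
                       np.zeros((4, 50)), np.zeros(50))
        tokens = np.arange(50)
        assert perplexity(w, tokens, pad_id=0) == pytest.approx(50.0)

    def test_proper_model_never_below_one(self):
        w = init_weights(InitSpec(seed=1), "lstm", 16, 4)
        tokens = np.random.default_rng(0).integers(0, 16, 200)
        assert perplexity(w, tokens, pad_id=0) >= 1.0

    def test_empty_test_set_rejected(self):
        w = init_weights(InitSpec(seed=0), "srn", 8, 4)
        with pytest.raises(InvalidConfigError):
            perplexity(w, np.array([], dtype=int), pad_id=0)


class TestThresholdGrid:
    def test_default_grid_is_0_to_1_step_0_001(self):
        grid = ThresholdGrid().values()
        assert grid.shape[0] == 1001
        assert grid[0] == 0.0 and grid[-1] == pytest.approx(1.0)
        assert np.all(np.diff(grid) > 0)


class TestBalancedAccuracySweep:
    def test_oracle_matrix_gives_perfect_score(self):
        words = ["a1", "a2", "b1", "b2"]
        cats = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = v[2, 3] = v[3, 2] = 1.0
        np.fill_diagonal(v, 1.0)
        report = balanced_accuracy_sweep(_sim(v, words), ProbeSet(probes=cats))
        assert report.mean_balanced_accuracy == 1.0

    def test_hand_built_matrix_matches_enumeration(self):
        words = ["a1", "a2", "b1", "b2"]
        cats = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        rng = np.random.default_rng(3)
        v = rng.uniform(0, 1, (4, 4))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        grid = ThresholdGrid(step=0.01)
        report = balanced_accuracy_sweep(_sim(v, words), ProbeSet(probes=cats), grid)
        curve, best_thr, best_val = brute_force_sweep(
            v, [cats[w] for w in words], grid.values()
        )
        assert np.allclose(report.balanced_accuracy.mean(axis=0), curve)
        assert report.mean_balanced_accuracy == pytest.approx(best_val)
        assert report.best_threshold == pytest.approx(best_thr)

    def test_probe_order_invariance(self):
        rng = np.random.default_rng(5)
        words = [f"w{i}" for i in range(6)]
        cats = {w: f"c{i % 2}" for i, w in enumerate(words)}
        v = rng.uniform(0, 1, (6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        r1 = balanced_accuracy_sweep(_sim(v, words), ProbeSet(probes=cats))
        perm = [3, 0, 5, 1, 4, 2]
        v2 = v[np.ix_(perm, perm)]
        words2 = [words[i] for i in perm]
        r2 = balanced_accuracy_sweep(_sim(v2, words2), ProbeSet(probes=cats))
        assert r1.mean_balanced_accuracy == pytest.approx(r2.mean_balanced_accuracy)
        assert r1.per_probe_at_best.sort_index().equals(
            r2.per_probe_at_best.sort_index()
        )

    def test_ties_at_threshold_count_as_different(self):
        # one same-category pair with S exactly at a grid value: it is a
        # miss there, so sensitivity at that threshold is 0
        words = ["a1", "a2", "b1"]
        cats = {"a1": "A", "a2": "A", "b1": "B"}
        v = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        report = balanced_accuracy_sweep(
            _sim(v, words), ProbeSet(probes=cats), ThresholdGrid(step=0.5)
        )
        i = list(report.thresholds).index(0.5)
        assert report.sensitivity[0, i] == 0.0

    def test_probe_without_partner_excluded(self):
        words = ["a1", "a2", "solo"]
        cats = {"a1": "A", "a2": "A", "solo": "S"}
        v = np.eye(3)
        report = balanced_accuracy_sweep(_sim(v, words), ProbeSet(probes=cats))
        assert "solo" not in report.probe_words

    def test_nonsquare_matrix_rejected(self):
        s = SimilarityMatrix(values=np.zeros((2, 3)), row_words=["a", "b"],
                             col_words=["a", "b", "c"])
        with pytest.raises(InvalidConfigError):
            balanced_accuracy_sweep(s, ProbeSet(probes={"a": "A", "b": "A"}))


class TestNearestNeighbors:
    WORDS = ["a", "b", "c", "d", "e"]

    def _space(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(-1, 1, (5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        return _sim(v, self.WORDS)

    def test_k_zero_gives_empty_list(self):
        assert nearest_neighbors(self._space(), "a", 0) == []

    def test_duplicate_word_ranks_first_with_unit_similarity(self):
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 1.0
        out = nearest_neighbors(_sim(v, ["w", "x", "y"]), "w", 2)
        assert out[0] == ("x", 1.0)

    def test_ranking_matches_brute_force_sort(self):
        s = self._space()
        got = nearest_neighbors(s, "c", 4)
        i = self.WORDS.index("c")
        pairs = [(w, float(s.values[i, j])) for j, w in enumerate(self.WORDS)
                 if w != "c"]
        expected = sorted(pairs, key=lambda p: (-p[1], p[0]))
        assert got == expected

    def test_unknown_word_rejected(self):
        with pytest.raises(KeyError):
            nearest_neighbors(self._space(), "zzz", 3)


class TestCategoryMatrix:
    def test_perfect_block_structure(self):
        words = ["a1", "a2", "b1", "b2"]
        cats = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = v[2, 3] = v[3, 2] = 1.0
        np.fill_diagonal(v, 1.0)
        out = category_similarity_matrix(_sim(v, words), ProbeSet(probes=cats))
        expect = np.eye(2)
        assert np.allclose(out.values, expect)

    def test_constant_similarities_give_constant_matrix(self):
        words = ["a1", "a2", "b1", "b2"]
        cats = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        v = np.full((4, 4), 0.3)
        np.fill_diagonal(v, 1.0)  # diagonal removed before averaging
        out = category_similarity_matrix(_sim(v, words), ProbeSet(probes=cats))
        assert np.allclose(out.values, 0.3)

    def test_cells_match_brute_force_pair_averaging(self):
        words = ["a1", "a2", "a3", "b1", "b2", "b3"]
        cats = {w: ("A" if w.startswith("a") else "B") for w in words}
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 1, (6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        out = category_similarity_matrix(_sim(v, words), ProbeSet(probes=cats))
        df = out.to_frame()
        a_idx, b_idx = [0, 1, 2], [3, 4, 5]
        within_a = np.mean([v[i, j] for i in a_idx for j in a_idx if i != j])
        between = np.mean([v[i, j] for i in a_idx for j in b_idx])
        assert df.loc["A", "A"] == pytest.approx(within_a)
        assert df.loc["A", "B"] == pytest.approx(between)

    def test_permuted_probe_list_gives_same_cells(self):
        words = ["a1", "a2", "b1", "b2", "c1", "c2"]
        cats = {w: w[0].upper() for w in words}
        rng = np.random.default_rng(4)
        v = rng.uniform(0, 1, (6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        out1 = category_similarity_matrix(_sim(v, words), ProbeSet(probes=cats))
        perm = [5, 2, 0, 4, 1, 3]
        out2 = category_similarity_matrix(
            _sim(v[np.ix_(perm, perm)], [words[i] for i in perm]),
            ProbeSet(probes=cats),
        )
        c = sorted(out1.categories)
        assert np.allclose(
            out1.to_frame().loc[c, c].values, out2.to_frame().loc[c, c].values
        )


class TestHierarchicalCluster:
    def test_identical_items_merge_at_zero_distance(self):
        v = np.ones((2, 2))
        d = hierarchical_cluster(_sim(v, ["a", "b"]))
        assert d.linkage[0, 2] == pytest.approx(0.0)

    def test_tight_pair_merges_first(self):
        v = np.array([[1.0, 0.9, 0.1],
                      [0.9, 1.0, 0.2],
                      [0.1, 0.2, 1.0]])
        d = hierarchical_cluster(_sim(v, ["x", "y", "z"]))
        first = sorted(d.linkage[0, :2].astype(int))
        assert first == [0, 1]  # x and y join before z

    def test_block_structure_gives_contiguous_leaves(self):
        rng = np.random.default_rng(0)
        n = 8
        v = rng.uniform(0.0, 0.2, (n, n))
        v[:4, :4] += 0.7
        v[4:, 4:] += 0.7
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        words = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        d = hierarchical_cluster(_sim(v, words))
        labels = [w[0] for w in d.leaf_order]
        assert labels == sorted(labels) or labels == sorted(labels, reverse=True)

    def test_newick_export_contains_all_leaves(self):
        v = np.eye(3) * 0.5 + 0.5
        nwk = hierarchical_cluster(_sim(v, ["x", "y", "z"])).to_newick()
        assert nwk.endswith(";")
        for leaf in ("x", "y", "z"):
            assert leaf in nwk

    def test_single_item_rejected(self):
        with pytest.raises(InvalidConfigError):
            hierarchical_cluster(_sim(np.ones((1, 1)), ["a"]))


class TestPCA:
    def _reps(self, mat):
        mat = np.asarray(mat, dtype=float)
        return RepresentationMatrix(
            words=[f"w{i}" for i in range(mat.shape[0])],
            matrix=mat,
            occurrence_counts=np.ones(mat.shape[0], dtype=int),
        )

    def test_one_dimensional_data_loads_on_single_component(self):
        t = np.linspace(-1, 1, 10)
        mat = np.outer(t, [1.0, 2.0, -1.0])
        report = pca_loadings(self._reps(mat))
        assert report.variance_fractions[0] == pytest.approx(1.0)

    def test_isotropic_data_splits_variance_evenly(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(500, 2))
        report = pca_loadings(self._reps(mat))
        assert report.variance_fractions[0] == pytest.approx(0.5, abs=0.1)
        assert report.variance_fractions[1] == pytest.approx(0.5, abs=0.1)

    def test_fractions_nonnegative_and_sum_at_most_one(self):
        rng = np.random.default_rng(1)
        report = pca_loadings(self._reps(rng.normal(size=(20, 6))))
        assert np.all(report.variance_fractions >= 0)
        assert report.variance_fractions.sum() <= 1.0 + 1e-9

    def test_single_row_rejected(self):
        with pytest.raises(InvalidConfigError):
            pca_loadings(self._reps(np.ones((1, 4))))

    def test_leading_component_separates_planted_classes(self, small_planted):
        # scaled-down analogue of a grammatical noun/not-noun component:
        # with two planted categories the dominant structure in trained
        # hidden representations separates the category memberships
        from semlearn.corpus import BOUNDARY, UNKNOWN, build_vocabulary, encode_corpus
        from semlearn.model import RecurrentLanguageModel
        from semlearn.training import TrainingConfig

        _, _, corpus, probes = small_planted
        vocab = build_vocabulary(corpus, 64, extra_symbols=(UNKNOWN, BOUNDARY))
        tokens = np.concatenate(encode_corpus(corpus, vocab))
        model = RecurrentLanguageModel.from_tokens(tokens, vocab, 2, arch="srn")
        res = model.fit(TrainingConfig(local_iterations=2, hidden_size=16, seed=2))
        reps = res.representations(tokens).defined_subset(sorted(probes))
        report = pca_loadings(reps, n_components=2)
        labels = np.array([probes[w] == probes[sorted(probes)[0]]
                           for w in report.loadings.index], dtype=float)
        best = max(
            abs(np.corrcoef(report.loadings[pc], labels)[0, 1])
            for pc in ("PC1", "PC2")
        )
        assert best > 0.8
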