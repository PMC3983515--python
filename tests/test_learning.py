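"""Training agglomeration, edge labels, policies and persistence."""

import numpy as np
import pytest

from ragseg import Rag, build_rag
from ragseg.evaluate import vi
from ragseg.features import MomentsManager, default_manager
from ragseg.learning import (
    classifier_probability,
    default_classifier,
    deserialize_policy,
    edge_label,
    flat_learning,
    learn_agglomerate,
    mean_boundary_policy,
    median_boundary_policy,
    serialize_policy,
    TrainingSet,
)


class TestEdgeLabel:
    def test_same_gold_body_should_merge(self):
        sp = np.array([[1, 1, 2, 2]])
        gold = np.array([[7, 7, 7, 7]])
        g = build_rag(sp, np.zeros((1, 4)))
        assert edge_label(g, 1, 2, gold) == -1

    def test_different_gold_bodies_should_not_merge(self):
        sp = np.array([[1, 1, 2, 2]])
        gold = np.array([[7, 7, 8, 8]])
        g = build_rag(sp, np.zeros((1, 4)))
        assert edge_label(g, 1, 2, gold) == 1

    def test_impure_node_ambiguous(self):
        # node 1 overlaps gold bodies 55% / 45%: below purity 0.75
        sp = np.array([[1] * 20 + [2] * 4])
        gold = np.array([[7] * 11 + [8] * 13])
        g = build_rag(sp, np.zeros((1, 24)))
        assert edge_label(g, 1, 2, gold, purity_min=0.75) == 0
        # with a laxer purity the plurality bodies (7 vs 8) disagree
        assert edge_label(g, 1, 2, gold, purity_min=0.5) == 1

    def test_zero_gold_overlap_ambiguous(self):
        sp = np.array([[1, 1, 2, 2]])
        gold = np.array([[0, 0, 3, 3]])
        g = build_rag(sp, np.zeros((1, 4)))
        assert edge_label(g, 1, 2, gold) == 0

    def test_symmetry(self, noisy_2d):
        _, gold, prob, sp = noisy_2d
        g = build_rag(sp, prob)
        for u, v in list(g.graph.edges)[:10]:
            assert edge_label(g, u, v, gold) == edge_label(g, v, u, gold)


class TestFlatLearning:
    def test_sample_count_is_unambiguous_edges(self, noiseless_2d):
        _, gold, prob, sp = noiseless_2d
        g = build_rag(sp, prob)
        ts = flat_learning(g, gold)
        n_ambiguous = sum(
            edge_label(g, u, v, gold) == 0 for u, v in g.graph.edges
        )
        assert len(ts) == g.graph.number_of_edges() - n_ambiguous
        assert ts.features.shape[1] == g.manager.feature_length

    def test_noiseless_classes_linearly_separable(self, noiseless_2d):
        """On a clean boundary map the mean-boundary feature separates
        true from false merges perfectly."""
        _, gold, prob, sp = noiseless_2d
        g = build_rag(sp, prob)
        ts = flat_learning(g, gold)
        clf = default_classifier(0, 25)
        clf.fit(ts.features, ts.labels)
        assert np.all(clf.predict(ts.features) == ts.labels)

    def test_flat_is_level_zero_slice_of_epoch_one(self, noiseless_2d):
        """Epoch-1 samples taken while both endpoints are still initial
        superpixels coincide with flat samples for those edges."""
        _, gold, prob, sp = noiseless_2d
        g = build_rag(sp, prob)
        flat = flat_learning(g, gold)
        flat_by_edge = {e: i for i, e in enumerate(flat.edges)}
        g2 = build_rag(sp, prob)
        ts = learn_agglomerate(g2, gold, n_epochs=1)
        initial = set(int(l) for l in np.unique(sp) if l > 0)
        n_level0 = 0
        for i, (u, v) in enumerate(ts.edges):
            if u in initial and v in initial and (u, v) in flat_by_edge:
                j = flat_by_edge[(u, v)]
                assert ts.labels[i] == flat.labels[j]
                np.testing.assert_allclose(ts.features[i], flat.features[j])
                n_level0 += 1
        assert n_level0 > 0


class TestLearnAgglomerate:
    def test_rejects_zero_epochs(self, noiseless_2d):
        _, gold, prob, sp = noiseless_2d
        g = build_rag(sp, prob)
        with pytest.raises(ValueError):
            learn_agglomerate(g, gold, n_epochs=0)

    def test_noiseless_training_agglomeration_reproduces_gold(self, noiseless_2d):
        """Guided merging executes every true merge and no false one, so
        the epoch's final graph state matches the gold standard."""
        _, gold, prob, sp = noiseless_2d
        g = build_rag(sp, prob)
        ts = learn_agglomerate(g, gold, n_epochs=1)
        assert vi(g.current_segmentation(), gold) == pytest.approx(0.0, abs=1e-12)
        assert set(np.unique(ts.labels)) == {-1, 1}

    def test_sample_count_bounded_by_edge_hierarchy(self, noisy_2d):
        _, gold, prob, sp = noisy_2d
        g = build_rag(sp, prob)
        e0 = g.n_initial_edges
        n_epochs = 2
        ts = learn_agglomerate(
            g, gold, n_epochs=n_epochs,
            classifier_factory=lambda: default_classifier(0, 10),
        )
        assert len(ts) <= n_epochs * 2 * e0

    def test_single_gold_body_degenerate_flagged(self):
        sp = np.tile(np.array([[1, 2], [3, 4]]), (2, 2))
        gold = np.ones((4, 4), dtype=int)
        rng = np.random.default_rng(0)
        g = build_rag(sp, rng.random((4, 4)))
        ts = learn_agglomerate(g, gold, n_epochs=1)
        assert ts.degenerate_gold
        assert np.all(ts.labels == -1)

    def test_deterministic_across_runs(self, noisy_2d):
        _, gold, prob, sp = noisy_2d
        results = []
        for _ in range(2):
            g = build_rag(sp, prob)
            ts = learn_agglomerate(
                g, gold, n_epochs=2,
                classifier_factory=lambda: default_classifier(7, 15),
            )
            results.append(ts)
        np.testing.assert_array_equal(results[0].features, results[1].features)
        np.testing.assert_array_equal(results[0].labels, results[1].labels)
        assert results[0].edges == results[1].edges


class _ConstantClassifier:
    classes_ = np.array([-1, 1])

    def predict_proba(self, X):
        return np.full((len(X), 2), 0.5)


class _MeanFeatureClassifier:
    """Monotone in the mean-boundary feature (index 1 of moments-only
    edge vectors): priority ordering must match mean-boundary ordering."""

    classes_ = np.array([-1, 1])

    def predict_proba(self, X):
        p = 1 / (1 + np.exp(-X[:, 1]))
        return np.column_stack([1 - p, p])


class TestPolicies:
    def test_constant_half_policy_merges_nothing(self, noisy_2d):
        _, _, prob, sp = noisy_2d
        g = build_rag(sp, prob)
        policy = classifier_probability(g.manager, _ConstantClassifier())
        seg = g.agglomerate(policy, 0.5)
        assert vi(seg, sp) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_classifier_preserves_mean_ordering(self, noisy_2d):
        from scipy.stats import spearmanr

        _, _, prob, sp = noisy_2d
        g = Rag(sp, prob, manager=MomentsManager(2))
        policy = classifier_probability(g.manager, _MeanFeatureClassifier())
        mean_policy = mean_boundary_policy()
        edges = sorted(tuple(sorted(e)) for e in g.graph.edges)
        learned = [policy(g, u, v) for u, v in edges]
        means = [mean_policy(g, u, v) for u, v in edges]
        rho, _ = spearmanr(learned, means)
        assert rho == pytest.approx(1.0)

    def test_unfitted_classifier_raises_on_first_call(self, noisy_2d):
        _, _, prob, sp = noisy_2d
        g = build_rag(sp, prob)
        policy = classifier_probability(g.manager, default_classifier(0))
        u, v = next(iter(g.graph.edges))
        with pytest.raises(RuntimeError):
            policy(g, u, v)

    def test_mean_boundary_examples(self):
        g = build_rag(
            np.array([[1, 1, 2, 2]]), np.array([[0.0, 0.2, 0.4, 0.0]])
        )
        assert mean_boundary_policy()(g, 1, 2) == pytest.approx(0.3)

    def test_median_boundary_within_bin_width(self):
        g = build_rag(
            np.array([[1, 2], [1, 2]]),
            np.array([[0.1, 0.9], [0.9, 0.9]]),
        )
        # sort oracle: boundary pixels hold {0.1, 0.9, 0.9, 0.9}; median 0.9
        est = median_boundary_policy(n_bins=25)(g, 1, 2)
        assert abs(est - 0.9) <= 1 / 25

    def test_mean_invariant_to_boundary_split(self, noisy_2d):
        """The mean priority of a post-merge edge equals the pixel mean
        over the union of the two pre-merge boundary sets."""
        _, _, prob, sp = noisy_2d
        g = build_rag(sp, prob)
        for u, v in (tuple(sorted(e)) for e in g.graph.edges):
            common = set(g.graph[u]) & set(g.graph[v])
            if common:
                x = min(common)
                union = np.union1d(
                    g.boundary_pixels(u, x), g.boundary_pixels(v, x)
                )
                expected = g.pixel_values(union)[:, 0].mean()
                w = g.merge_nodes(u, v)
                assert mean_boundary_policy()(g, w, x) == pytest.approx(expected)
                break


class TestPersistence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_reproduces_priorities_bitwise(
        self, tmp_path, noisy_2d, seed
    ):
        _, gold, prob, sp = noisy_2d
        g = build_rag(sp, prob)
        ts = learn_agglomerate(
            g, gold, n_epochs=1,
            classifier_factory=lambda: default_classifier(seed, 10),
        )
        clf = default_classifier(seed, 10)
        clf.fit(ts.features, ts.labels)
        policy = classifier_probability(g.manager, clf)
        serialize_policy(policy, tmp_path / f"bundle{seed}")
        loaded = deserialize_policy(tmp_path / f"bundle{seed}")

        g2 = build_rag(sp, prob, manager=loaded.manager)
        edges = sorted(tuple(sorted(e)) for e in g2.graph.edges)
        original = [policy(g2, u, v) for u, v in edges]
        restored = [loaded(g2, u, v) for u, v in edges]
        assert original == restored  # bit-identical

    def test_empty_path_rejected(self, noisy_2d):
        policy = classifier_probability(default_manager(), _ConstantClassifier())
        with pytest.raises(ValueError):
            serialize_policy(policy, "")

    def test_version_mismatch_rejected(self, tmp_path):
        import json

        policy = classifier_probability(default_manager(), _ConstantClassifier())
        serialize_policy(policy, tmp_path / "b")
        with open(tmp_path / "b" / "manager.json", "w") as f:
            json.dump({"version": 999, "manager": {"name": "moments"}}, f)
        with pytest.raises(ValueError):
            deserialize_policy(tmp_path / "b")

    def test_training_set_h5_round_trip(self, tmp_path, noiseless_2d):
        _, gold, prob, sp = noiseless_2d
        g = build_rag(sp, prob)
        ts = flat_learning(g, gold)
        ts.save(tmp_path / "ts.h5")
        loaded = TrainingSet.load(tmp_path / "ts.h5")
        np.testing.assert_array_equal(loaded.features, ts.features)
        np.testing.assert_array_equal(loaded.labels, ts.labels)
        np.testing.assert_array_equal(loaded.epochs, ts.epochs)
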