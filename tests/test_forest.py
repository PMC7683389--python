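import json

import numpy as np
import pytest

from gerforest import (
    ForestConfig,
    NodePopulation,
    PartiallyLabeledDataset,
    best_threshold,
    generate_candidates,
    grow_tree,
    load_forest,
    optimal_threshold,
    predict,
    save_forest,
    select_split,
    synthetic,
    train_forest,
)
from gerforest.forest import _flatten_tree


class TestGenerateCandidates:
    def test_deterministic_given_seed(self):
        a = generate_candidates(5, 3, np.random.default_rng(9))
        b = generate_candidates(5, 3, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_candidate_structure(self):
        W = generate_candidates(10, 200, np.random.default_rng(0), n_nonzero=2)
        for w in W:
            nz = np.nonzero(w)[0]
            if nz.size == 1 and w[nz[0]] == 1.0:
                continue  # axis-aligned: single entry equal to 1
            assert nz.size <= 2
            assert np.all(np.abs(w[nz]) <= 1.0)

    def test_mixes_both_kinds(self):
        W = generate_candidates(10, 100, np.random.default_rng(1))
        axis = sum(1 for w in W if np.count_nonzero(w) == 1 and w.max() == 1.0)
        assert 0 < axis < 100


class TestOptimalThreshold:
    def test_midpoint_between_separated_classes(self):
        # projections (0, 1 | 9, 10): the best midpoint is (1+9)/2 = 5
        tau, gain = best_threshold(
            np.array([0.0, 1.0, 9.0, 10.0]), np.array([0, 0, 1, 1]), 2
        )
        assert tau == pytest.approx(5.0)
        assert gain == pytest.approx(0.5)

    def test_single_class_is_invalid(self):
        assert best_threshold(np.array([0.0, 1.0]), np.array([0, 0]), 2) is None

    def test_identical_projections_invalid(self):
        assert best_threshold(np.array([2.0, 2.0]), np.array([0, 1]), 2) is None

    def test_duplicate_projections_use_distinct_midpoints(self):
        # values (0, 0, 1): only one candidate threshold at 0.5
        tau, _ = best_threshold(np.array([0.0, 0.0, 1.0]), np.array([0, 0, 1]), 2)
        assert tau == pytest.approx(0.5)

    def test_tie_broken_to_smallest_threshold(self):
        # (0, 1, 2, 3) labels (0, 0, 1, 1) -- only 1.5 is optimal; but
        # labels (0, 1, 0, 1) gives equal-gain candidates: smallest wins
        tau, _ = best_threshold(
            np.array([0.0, 1.0, 2.0, 3.0]), np.array([0, 1, 0, 1]), 2
        )
        assert tau == pytest.approx(0.5)

    def test_population_wrapper(self):
        ds = PartiallyLabeledDataset(
            X_labeled=np.array([[0.0], [1.0], [9.0], [10.0]]),
            y_labeled=np.array([0, 0, 1, 1]),
            X_unlabeled=np.empty((0, 1)),
            n_classes=2,
        )
        pop = NodePopulation(labeled_ids=np.arange(4))
        tau, gain = optimal_threshold(np.array([1.0]), pop, ds, ds.y_labeled)
        assert tau == pytest.approx(5.0) and gain == pytest.approx(0.5)


class TestSelectSplit:
    def test_pseudo_labels_reverse_candidate_ranking(self):
        """Unlabeled cluster structure decides where labels are ambiguous.

        Two candidates both separate the labeled pair perfectly; only
        the x-axis split respects the pseudo-labeled clusters, so the
        graph criterion picks it while the supervised criterion keeps
        the first candidate (the y-axis split) by tie-break order.
        """
        X_l = np.array([[-1.0, -1.0], [1.0, 1.0]])
        y = np.array([0, 1])
        X_u = np.array([[-2.0, 1.0], [-2.0, -1.0], [2.0, 1.0], [2.0, -1.0]])
        pseudo = np.array([0, 0, 1, 1])
        ds = PartiallyLabeledDataset(
            X_labeled=X_l, y_labeled=y, X_unlabeled=X_u, n_classes=2
        )
        pop = NodePopulation(labeled_ids=np.arange(2), unlabeled_ids=np.arange(4))
        candidates = [
            (np.array([0.0, 1.0]), 0.0),  # y-axis split: mixes the clusters
            (np.array([1.0, 0.0]), 0.0),  # x-axis split: respects them
        ]
        chosen_graph = select_split(candidates, pop, ds, y, pseudo, 2, variant="graph")
        chosen_std = select_split(candidates, pop, ds, y, pseudo, 2, variant="standard")
        np.testing.assert_array_equal(chosen_graph.weights, [1.0, 0.0])
        np.testing.assert_array_equal(chosen_std.weights, [0.0, 1.0])


class TestGrowTree:
    def test_separable_data_yields_pure_training_predictions(self):
        full = synthetic.make_clusters(n_per_class=30, noise_scale=0.3, seed=5)
        cfg = ForestConfig(max_depth=10, min_labeled_split=2)
        tree = grow_tree(full, cfg, variant="standard", seed=3)
        forest = _single_tree_forest(tree, full)
        acc = np.mean(forest.predict(full.X_labeled) == full.y_labeled)
        assert acc == 1.0

    def test_zero_depth_gives_single_leaf(self):
        full = synthetic.make_clusters(n_per_class=10, seed=1)
        cfg = ForestConfig(max_depth=0)
        tree = grow_tree(full, cfg, variant="standard", seed=0)
        assert tree.is_leaf
        # root distribution reflects the (smoothed) class balance
        np.testing.assert_allclose(tree.distribution, [0.5, 0.5])

    def test_membership_conserved_at_every_node(self, moons_ssl):
        pseudo = moons_ssl.y_unlabeled_oracle  # any valid label vector works
        cfg = ForestConfig(max_depth=6, min_labeled_split=2)
        tree = grow_tree(moons_ssl, cfg, variant="graph", pseudo=pseudo, seed=2)

        def count(node, X):
            if node.is_leaf:
                return X.shape[0]
            mask = node.split.goes_left(X)
            return count(node.left, X[mask]) + count(node.right, X[~mask])

        total = count(tree, moons_ssl.all_features())
        assert total == moons_ssl.n_labeled + moons_ssl.n_unlabeled

    def test_depth_monotonicity_of_training_accuracy(self):
        full = synthetic.make_moons(n_per_class=50, noise_scale=0.2, seed=8)
        accs = []
        for depth in range(0, 6):
            cfg = ForestConfig(
                n_trees=1, bootstrap=False, max_depth=depth, min_labeled_split=2, seed=4
            )
            forest = train_forest(full, cfg, variant="standard")
            accs.append(np.mean(forest.predict(full.X_labeled) == full.y_labeled))
        assert all(b >= a for a, b in zip(accs, accs[1:]))


class TestTrainForest:
    def test_single_class_rejected(self):
        ds = PartiallyLabeledDataset(
            X_labeled=np.random.default_rng(0).standard_normal((10, 2)),
            y_labeled=np.zeros(10, int),
            X_unlabeled=np.empty((0, 2)),
            n_classes=1,
        )
        with pytest.raises(ValueError, match="distinct classes"):
            train_forest(ds, ForestConfig(n_trees=1))

    def test_same_seed_bit_identical(self, moons_ssl, small_config, tmp_path):
        f1 = train_forest(moons_ssl, small_config, variant="graph")
        f2 = train_forest(moons_ssl, small_config, variant="graph")
        save_forest(f1, tmp_path / "a.json")
        save_forest(f2, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_supervised_limit_variants_identical(self):
        """With u = 0 the graph and standard forests match node for node."""
        full = synthetic.make_moons(n_per_class=40, noise_scale=0.1, seed=6)
        cfg = ForestConfig(n_trees=3, seed=13)
        f_graph = train_forest(full, cfg, variant="graph")
        f_std = train_forest(full, cfg, variant="standard")
        for tg, ts in zip(f_graph.trees, f_std.trees):
            assert _flatten_tree(tg) == _flatten_tree(ts)

    def test_prediction_rows_sum_to_one(self, moons_ssl, small_config, rng):
        forest = train_forest(moons_ssl, small_config, variant="standard")
        X = rng.standard_normal((20, 2))
        proba = predict(forest, X)
        np.testing.assert_allclose(proba.sum(axis=1), np.ones(20), atol=1e-12)

    def test_dimension_mismatch_rejected(self, moons_ssl, small_config):
        forest = train_forest(moons_ssl, small_config, variant="standard")
        with pytest.raises(ValueError, match="query matrix"):
            predict(forest, np.zeros((3, 7)))

    def test_single_tree_forest_equals_grow_tree(self):
        full = synthetic.make_clusters(n_per_class=20, seed=2)
        cfg = ForestConfig(n_trees=1, bootstrap=False, seed=21)
        forest = train_forest(full, cfg, variant="standard")
        seed = int(
            (np.random.SeedSequence(21).generate_state(1, dtype=np.uint32) & 0x7FFFFFFF)[0]
        )
        tree = grow_tree(full, cfg, variant="standard", seed=seed)
        assert _flatten_tree(forest.trees[0]) == _flatten_tree(tree)


class TestSerialization:
    def test_round_trip_preserves_predictions(self, moons_ssl, small_config, tmp_path, rng):
        forest = train_forest(moons_ssl, small_config, variant="graph")
        save_forest(forest, tmp_path / "model.json")
        loaded = load_forest(tmp_path / "model.json")
        X = rng.standard_normal((50, 2))
        np.testing.assert_array_equal(predict(forest, X), predict(loaded, X))

    def test_load_save_byte_stable(self, moons_ssl, small_config, tmp_path):
        forest = train_forest(moons_ssl, small_config, variant="standard")
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        save_forest(forest, p1)
        save_forest(load_forest(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_truncated_file_rejected(self, moons_ssl, small_config, tmp_path):
        forest = train_forest(moons_ssl, small_config, variant="standard")
        p = tmp_path / "model.json"
        save_forest(forest, p)
        p.write_bytes(p.read_bytes()[: p.stat().st_size // 2])
        with pytest.raises(ValueError, match="truncated"):
            load_forest(p)

    def test_schema_version_mismatch_rejected(self, tmp_path):
        p = tmp_path / "model.json"
        p.write_text(json.dumps({"schema_version": 99, "config": {}, "trees": []}))
        with pytest.raises(ValueError, match="schema version"):
            load_forest(p)


def _single_tree_forest(tree, dataset):
    from gerforest.forest import Forest, ForestConfig

    return Forest(
        trees=[tree],
        n_classes=dataset.n_classes,
        n_features=dataset.n_features,
        variant="standard",
        config=ForestConfig(n_trees=1),
    )
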