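import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gerforest import (
    NodePopulation,
    PartiallyLabeledDataset,
    SplitFunction,
    gini_index,
    graph_embedded_gain,
    split_population,
    supervised_gain,
)


def _dataset(X_l, y_l, X_u, K=2, pseudo=None):
    ds = PartiallyLabeledDataset(
        X_labeled=np.atleast_2d(X_l).astype(float),
        y_labeled=np.asarray(y_l, int),
        X_unlabeled=np.atleast_2d(X_u).astype(float)
        if len(X_u)
        else np.empty((0, np.atleast_2d(X_l).shape[1])),
        n_classes=K,
    )
    return ds


class TestGiniIndex:
    def test_pure_node_is_zero(self):
        pop = NodePopulation(labeled_ids=np.arange(4))
        assert gini_index(pop, np.zeros(4, int), None, 2) == 0.0

    def test_balanced_mixed_node_is_half(self):
        # 2 labeled class 0 + 2 pseudo-labeled class 1
        pop = NodePopulation(labeled_ids=np.arange(2), unlabeled_ids=np.arange(2))
        g = gini_index(pop, np.zeros(2, int), np.ones(2, int), 2)
        assert g == pytest.approx(0.5)

    def test_three_to_one_mixture(self):
        # p = (3/4, 1/4) -> 2 * (3/4)(1/4) = 0.375
        pop = NodePopulation(labeled_ids=np.arange(3), unlabeled_ids=np.arange(1))
        g = gini_index(pop, np.zeros(3, int), np.ones(1, int), 2)
        assert g == pytest.approx(0.375)

    def test_empty_population_is_zero(self):
        pop = NodePopulation(labeled_ids=np.empty(0, int))
        assert gini_index(pop, np.empty(0, int), None, 3) == 0.0


class TestGraphEmbeddedGain:
    def test_perfect_split_of_pure_groups(self):
        # two pure pseudo-label groups of equal size, split cleanly
        ds = _dataset(
            X_l=np.empty((0, 1)).reshape(0, 1),
            y_l=[],
            X_u=[[-1.0], [-2.0], [1.0], [2.0]],
            pseudo=None,
        )
        pop = NodePopulation(labeled_ids=np.empty(0, int), unlabeled_ids=np.arange(4))
        pseudo = np.array([0, 0, 1, 1])
        split = SplitFunction(weights=np.array([1.0]), threshold=0.0)
        gain = graph_embedded_gain(pop, split, ds, np.empty(0, int), pseudo, 2)
        assert gain == pytest.approx(0.5)

    def test_one_sided_split_gains_zero(self):
        ds = _dataset(X_l=[[0.0], [1.0]], y_l=[0, 1], X_u=[])
        pop = NodePopulation(labeled_ids=np.arange(2))
        split = SplitFunction(weights=np.array([1.0]), threshold=100.0)
        gain = graph_embedded_gain(pop, split, ds, np.array([0, 1]), None, 2)
        assert gain == 0.0

    def test_matches_brute_force_recount(self, rng):
        """Gain equals an independent recount over explicit member lists."""
        for trial in range(30):
            nl, nu, K = rng.integers(1, 12), rng.integers(0, 12), int(rng.integers(2, 4))
            X_l = rng.standard_normal((nl, 3))
            X_u = rng.standard_normal((nu, 3))
            y = rng.integers(0, K, nl)
            pseudo = rng.integers(0, K, nu) if nu else None
            ds = _dataset(X_l, y, X_u if nu else [], K=K)
            pop = NodePopulation(labeled_ids=np.arange(nl), unlabeled_ids=np.arange(nu))
            w = rng.standard_normal(3)
            tau = float(rng.standard_normal())
            split = SplitFunction(weights=w, threshold=tau)
            gain = graph_embedded_gain(pop, split, ds, y, pseudo, K)

            # brute force: explicit membership loops, recomputing p_k from scratch
            def impurity(members):
                if not members:
                    return 0.0
                props = [
                    sum(1 for m in members if m[1] == k) / len(members)
                    for k in range(K)
                ]
                return sum(p * (1 - p) for p in props)

            members = [(X_l[i], y[i]) for i in range(nl)] + [
                (X_u[i], pseudo[i]) for i in range(nu)
            ]
            left = [m for m in members if float(np.dot(w, m[0])) < tau]
            right = [m for m in members if float(np.dot(w, m[0])) >= tau]
            expected = impurity(members) - (
                len(left) * impurity(left) + len(right) * impurity(right)
            ) / len(members)
            assert gain == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance(self, rng):
        X_l = rng.standard_normal((8, 2))
        y = rng.integers(0, 2, 8)
        ds = _dataset(X_l, y, [])
        split = SplitFunction(weights=rng.standard_normal(2), threshold=0.1)
        pop1 = NodePopulation(labeled_ids=np.arange(8))
        pop2 = NodePopulation(labeled_ids=rng.permutation(8))
        g1 = graph_embedded_gain(pop1, split, ds, y, None, 2)
        g2 = graph_embedded_gain(pop2, split, ds, y, None, 2)
        assert g1 == pytest.approx(g2, abs=1e-15)


class TestSupervisedGain:
    def test_hand_evaluated_axis_split(self):
        # classes at {0,1,2} and {8,9,10}; split at 5 is pure both sides
        X = np.array([[0.0], [1.0], [2.0], [8.0], [9.0], [10.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        ds = _dataset(X, y, [])
        pop = NodePopulation(labeled_ids=np.arange(6))
        split = SplitFunction(weights=np.array([1.0]), threshold=5.0)
        assert supervised_gain(pop, split, ds, y, 2) == pytest.approx(0.5)

    def test_equals_graph_gain_without_unlabeled(self, rng):
        for _ in range(10):
            X = rng.standard_normal((10, 2))
            y = rng.integers(0, 2, 10)
            ds = _dataset(X, y, [])
            pop = NodePopulation(labeled_ids=np.arange(10))
            split = SplitFunction(
                weights=rng.standard_normal(2), threshold=float(rng.standard_normal())
            )
            assert supervised_gain(pop, split, ds, y, 2) == graph_embedded_gain(
                pop, split, ds, y, None, 2
            )

    def test_unlabeled_only_node_is_an_error(self):
        ds = _dataset([[0.0]], [0], [[1.0], [2.0]])
        pop = NodePopulation(labeled_ids=np.empty(0, int), unlabeled_ids=np.arange(2))
        split = SplitFunction(weights=np.array([1.0]), threshold=1.5)
        with pytest.raises(ValueError, match="no labeled members"):
            supervised_gain(pop, split, ds, np.array([0]), 2)


class TestGainProperties:
    @settings(derandomize=True, max_examples=50)
    @given(
        labels=st.lists(st.integers(0, 2), min_size=1, max_size=20),
        pseudo=st.lists(st.integers(0, 2), max_size=20),
    )
    def test_gini_bounded_by_k_classes(self, labels, pseudo):
        """0 <= G(S) <= 1 - 1/K for any mixed population."""
        K = 3
        pop = NodePopulation(
            labeled_ids=np.arange(len(labels)), unlabeled_ids=np.arange(len(pseudo))
        )
        g = gini_index(
            pop, np.asarray(labels), np.asarray(pseudo) if pseudo else None, K
        )
        assert 0.0 <= g <= 1.0 - 1.0 / K + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(
        data=st.data(),
        n=st.integers(2, 15),
        tau=st.floats(-2.0, 2.0),
    )
    def test_gain_never_exceeds_parent_impurity(self, data, n, tau):
        """The weighted-children identity keeps gains within [.., G(S)]."""
        y = np.array(
            data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        )
        X = np.linspace(-1.0, 1.0, n).reshape(-1, 1)
        ds = _dataset(X, y, [])
        pop = NodePopulation(labeled_ids=np.arange(n))
        split = SplitFunction(weights=np.array([1.0]), threshold=tau)
        gain = graph_embedded_gain(pop, split, ds, y, None, 2)
        parent = gini_index(pop, y, None, 2)
        assert gain <= parent + 1e-12


class TestSplitPopulation:
    def test_children_partition_parent(self, rng):
        X_l = rng.standard_normal((12, 2))
        X_u = rng.standard_normal((7, 2))
        ds = _dataset(X_l, rng.integers(0, 2, 12), X_u)
        pop = NodePopulation(labeled_ids=np.arange(12), unlabeled_ids=np.arange(7))
        split = SplitFunction(weights=rng.standard_normal(2), threshold=0.0)
        left, right = split_population(pop, split, ds)
        assert left.size + right.size == pop.size
        np.testing.assert_array_equal(
            np.sort(np.concatenate([left.labeled_ids, right.labeled_ids])),
            np.arange(12),
        )
        np.testing.assert_array_equal(
            np.sort(np.concatenate([left.unlabeled_ids, right.unlabeled_ids])),
            np.arange(7),
        )
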