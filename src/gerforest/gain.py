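"""Node impurities and split gains over mixed labeled/pseudo-labeled populations.

A tree node's population is a pair of index lists into the labeled and
unlabeled blocks of a dataset.  The graph-embedded gain treats
pseudo-labeled members as first-class when counting class proportions:

    p_k = (#labeled members of class k + #unlabeled members pseudo-labeled k) / |S|
    G(S) = sum_k p_k (1 - p_k)
    gain(w, tau) = G(S) - (|S_left| G(S_left) + |S_right| G(S_right)) / |S|

with every member (labeled and unlabeled) routed through the split
``<w, x> < tau``.  The supervised gain is the same expression counting
labeled members only.  An empty node has impurity 0 by convention, which
makes the gain formula total; a split with an empty child then has gain
exactly 0.

Note on naming: child nodes are called left/right throughout; "labeled"
and "unlabeled" always refer to supervision status, never to sides of a
split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import PartiallyLabeledDataset


@dataclass
class SplitFunction:
    """Oblique binary test: ``<w, x> < tau`` routes LEFT (strict)."""

    weights: np.ndarray
    threshold: float

    def goes_left(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ np.asarray(self.weights, float) < self.threshold


@dataclass
class NodePopulation:
    """Index lists of a node's members in the labeled and unlabeled blocks."""

    labeled_ids: np.ndarray
    unlabeled_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.labeled_ids = np.asarray(self.labeled_ids, dtype=int)
        self.unlabeled_ids = np.asarray(self.unlabeled_ids, dtype=int)

    @property
    def size(self) -> int:
        return self.labeled_ids.size + self.unlabeled_ids.size


def _impurity_from_counts(counts: np.ndarray, kind: str = "gini") -> float:
    """Impurity of a count vector; an empty population is pure (0)."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    if kind == "gini":
        return float(1.0 - np.sum(p * p))
    if kind == "entropy":
        nz = p[p > 0]
        return float(-np.sum(nz * np.log2(nz)))
    raise ValueError(f"unknown impurity {kind!r}")


def population_counts(
    pop: NodePopulation,
    labels: np.ndarray,
    pseudo: np.ndarray | None,
    n_classes: int,
) -> np.ndarray:
    """Per-class member counts, summing labeled labels and pseudo-labels."""
    counts = np.bincount(labels[pop.labeled_ids], minlength=n_classes).astype(float)
    if pop.unlabeled_ids.size:
        if pseudo is None:
            raise ValueError("population has unlabeled members but no pseudo-labels")
        counts += np.bincount(pseudo[pop.unlabeled_ids], minlength=n_classes)
    return counts


def gini_index(
    pop: NodePopulation,
    labels: np.ndarray,
    pseudo: np.ndarray | None,
    n_classes: int,
) -> float:
    """Gini impurity of a node, counting labeled and pseudo-labeled members."""
    return _impurity_from_counts(population_counts(pop, labels, pseudo, n_classes))


def split_population(
    pop: NodePopulation,
    split: SplitFunction,
    dataset: PartiallyLabeledDataset,
) -> tuple[NodePopulation, NodePopulation]:
    """Route every member through the split; returns (left, right) children."""
    left_l = np.empty(0, dtype=int)
    right_l = np.empty(0, dtype=int)
    if pop.labeled_ids.size:
        mask = split.goes_left(dataset.X_labeled[pop.labeled_ids])
        left_l, right_l = pop.labeled_ids[mask], pop.labeled_ids[~mask]
    left_u = np.empty(0, dtype=int)
    right_u = np.empty(0, dtype=int)
    if pop.unlabeled_ids.size:
        mask = split.goes_left(dataset.X_unlabeled[pop.unlabeled_ids])
        left_u, right_u = pop.unlabeled_ids[mask], pop.unlabeled_ids[~mask]
    return NodePopulation(left_l, left_u), NodePopulation(right_l, right_u)


def graph_embedded_gain(
    parent: NodePopulation,
    split: SplitFunction,
    dataset: PartiallyLabeledDataset,
    labels: np.ndarray,
    pseudo: np.ndarray | None,
    n_classes: int,
) -> float:
    """Impurity decrease counting labeled AND pseudo-labeled members.

    Sizes |S|, |S_left|, |S_right| count all members.  A degenerate
    split (one child empty) yields gain exactly 0.
    """
    if parent.size == 0:
        raise ValueError("parent population is empty")
    left, right = split_population(parent, split, dataset)
    g_parent = gini_index(parent, labels, pseudo, n_classes)
    g_left = gini_index(left, labels, pseudo, n_classes)
    g_right = gini_index(right, labels, pseudo, n_classes)
    return g_parent - (left.size * g_left + right.size * g_right) / parent.size


def supervised_gain(
    parent: NodePopulation,
    split: SplitFunction,
    dataset: PartiallyLabeledDataset,
    labels: np.ndarray,
    n_classes: int,
    impurity: str = "gini",
) -> float:
    """Impurity decrease counting labeled members only.

    Raises if the parent has no labeled members (the gain is undefined
    and the candidate must be treated as invalid by the caller).
    """
    if parent.labeled_ids.size == 0:
        raise ValueError("supervised gain undefined: node has no labeled members")
    left, right = split_population(parent, split, dataset)
    counts = lambda p: np.bincount(labels[p.labeled_ids], minlength=n_classes).astype(float)
    n_parent = parent.labeled_ids.size
    n_left = left.labeled_ids.size
    n_right = right.labeled_ids.size
    g_parent = _impurity_from_counts(counts(parent), impurity)
    g_left = _impurity_from_counts(counts(left), impurity)
    g_right = _impurity_from_counts(counts(right), impurity)
    return g_parent - (n_left * g_left + n_right * g_right) / n_parent
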