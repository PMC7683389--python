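"""Random forests with a three-stage node construction and pluggable Stage 3.

Each internal node carries an oblique split ``<w, x> < tau`` built in
three stages:

1. draw a random set of candidate projection directions ``{w_j}``
   (axis-aligned one-hot vectors mixed with sparse oblique vectors);
2. for each candidate, pick the threshold ``tau_j`` maximizing the
   supervised information gain over the node's labeled members (sorted
   projections, midpoints between distinct values);
3. among the ``(w_j, tau_j)`` pairs, select the one maximizing a
   criterion that depends on the forest variant.

The semi-supervised ("graph") variant replaces only Stage 3: candidates
are scored by the graph-embedded Gini gain, routing the node's unlabeled
members by their propagated pseudo-labels, so unlabeled structure steers
split selection while thresholds, leaves and the entire testing path
remain those of a standard forest.  Oracle variants (perfect_stage3,
perfect_splitting, optimal) score stages with the withheld true labels
of the unlabeled block and serve as baselines/upper bounds.

Prediction averages the leaf class distributions reached in each tree;
the prediction code path is shared by every variant.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .datasets import PartiallyLabeledDataset
from .gain import NodePopulation, SplitFunction, _impurity_from_counts
from .propagation import propagate_dataset

SCHEMA_VERSION = 1

#: stage behaviors: (stage2 member scope, stage3 member scope)
#: scopes: "labeled" = labeled members with true labels;
#: "all_pseudo" = all members, unlabeled counted by pseudo-label;
#: "all_oracle" = all members, unlabeled counted by withheld true label.
VARIANT_STAGES: dict[str, tuple[str, str]] = {
    "standard": ("labeled", "labeled"),
    "control": ("labeled", "labeled"),
    "graph": ("labeled", "all_pseudo"),
    "perfect_stage3": ("labeled", "all_oracle"),
    "perfect_splitting": ("all_oracle", "all_oracle"),
    "optimal": ("all_oracle", "all_oracle"),
}

ORACLE_VARIANTS = {"perfect_stage3", "perfect_splitting", "optimal"}


@dataclass
class ForestConfig:
    """Hyperparameters of forest training and of the propagation step."""

    n_trees: int = 100
    n_candidates: int = 50  # candidates per node (Stage 1)
    n_nonzero: int = 2  # nonzeros of a sparse oblique candidate
    axis_fraction: float = 0.5  # expected share of axis-aligned candidates
    max_depth: int = 20
    min_labeled_split: int = 4
    bootstrap: bool = True  # bootstrap the labeled block per tree
    impurity: str = "gini"  # supervised criterion (gini or entropy)
    n_neighbors: int = 10  # t, affinity graph
    sigma: float | str = "auto"  # Gaussian bandwidth or median heuristic
    lam: float = 99.0  # propagation regularization
    leaves_use_pseudo: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TreeNode:
    """Either an internal node (split + two children) or a leaf."""

    split: SplitFunction | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    distribution: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return self.distribution is not None


@dataclass
class Forest:
    """Trained ensemble; ``trees`` are the root nodes."""

    trees: list
    n_classes: int
    n_features: int
    variant: str
    config: ForestConfig

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def generate_candidates(
    n_features: int,
    count: int,
    rng: np.random.Generator,
    n_nonzero: int = 2,
    axis_fraction: float = 0.5,
) -> np.ndarray:
    """Stage 1: draw ``count`` candidate projection vectors, shape (count, d).

    Each candidate is axis-aligned (a one-hot vector) with probability
    ``axis_fraction``, else sparse oblique with ``n_nonzero`` entries
    drawn uniformly from [-1, 1] on distinct coordinates.
    """
    if count < 1:
        raise ValueError("need at least one candidate")
    W = np.zeros((count, n_features))
    for j in range(count):
        if rng.random() < axis_fraction:
            W[j, rng.integers(n_features)] = 1.0
        else:
            s = min(n_nonzero, n_features)
            dims = rng.choice(n_features, size=s, replace=False)
            W[j, dims] = rng.uniform(-1.0, 1.0, size=s)
    return W


def best_threshold(
    proj: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    impurity: str = "gini",
) -> tuple[float, float] | None:
    """Stage 2: optimal threshold for one projection by exhaustive midpoints.

    Candidate thresholds are midpoints between consecutive distinct
    projected values; returns ``(tau, gain)`` maximizing the supervised
    gain (ties resolved to the smallest tau), or None when every
    projection coincides or fewer than two classes are present.
    """
    proj = np.asarray(proj, float)
    y = np.asarray(y, int)
    order = np.argsort(proj, kind="stable")
    p = proj[order]
    c = y[order]
    n = p.size
    if n < 2 or p[0] == p[-1] or np.unique(c).size < 2:
        return None
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), c] = 1.0
    cum = np.cumsum(onehot, axis=0)
    boundaries = np.nonzero(p[1:] > p[:-1])[0]  # split between b and b+1
    left_counts = cum[boundaries]
    total = cum[-1]
    right_counts = total - left_counts
    n_left = (boundaries + 1).astype(float)
    n_right = n - n_left

    def imp(counts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
        pk = counts / sizes[:, None]
        if impurity == "gini":
            return 1.0 - np.sum(pk * pk, axis=1)
        if impurity == "entropy":
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(pk > 0, pk * np.log2(pk), 0.0)
            return -np.sum(term, axis=1)
        raise ValueError(f"unknown impurity {impurity!r}")

    parent_imp = _impurity_from_counts(total, impurity)
    weighted = (n_left * imp(left_counts, n_left) + n_right * imp(right_counts, n_right)) / n
    gains = parent_imp - weighted
    j = int(np.argmax(gains))  # first max = smallest threshold
    tau = 0.5 * (p[boundaries[j]] + p[boundaries[j] + 1])
    return float(tau), float(gains[j])


def optimal_threshold(
    w: np.ndarray,
    pop: NodePopulation,
    dataset: PartiallyLabeledDataset,
    labels: np.ndarray,
    impurity: str = "gini",
) -> tuple[float, float] | None:
    """Stage 2 on a node population's labeled members (public wrapper)."""
    proj = dataset.X_labeled[pop.labeled_ids] @ np.asarray(w, float)
    return best_threshold(proj, labels[pop.labeled_ids], dataset.n_classes, impurity)


def _counts_gain(
    left_counts: np.ndarray,
    right_counts: np.ndarray,
    impurity: str,
) -> float:
    """Size-weighted impurity decrease from explicit child count vectors."""
    parent = left_counts + right_counts
    n = parent.sum()
    if n == 0:
        return 0.0
    nl, nr = left_counts.sum(), right_counts.sum()
    g = _impurity_from_counts(parent, impurity)
    gl = _impurity_from_counts(left_counts, impurity)
    gr = _impurity_from_counts(right_counts, impurity)
    return g - (nl * gl + nr * gr) / n


class _TreeGrower:
    """Grows one tree on tree-local data blocks.

    ``X_labeled``/``y_labeled`` are the tree's (possibly bootstrapped)
    labeled block; the unlabeled block is shared across trees.
    ``stage3_labels_u`` carries the per-unlabeled-instance labels used by
    Stage 3 (pseudo-labels for the graph variant, withheld true labels
    for oracle variants, None for supervised variants).
    """

    def __init__(
        self,
        X_labeled: np.ndarray,
        y_labeled: np.ndarray,
        X_unlabeled: np.ndarray,
        n_classes: int,
        variant: str,
        config: ForestConfig,
        tree_seed: int,
        stage3_labels_u: np.ndarray | None,
        oracle_labels_u: np.ndarray | None,
    ) -> None:
        self.X_l = X_labeled
        self.y_l = y_labeled
        self.X_u = X_unlabeled
        self.K = n_classes
        self.variant = variant
        self.cfg = config
        self.tree_seed = int(tree_seed)
        self.stage2_scope, self.stage3_scope = VARIANT_STAGES[variant]
        self.stage3_labels_u = stage3_labels_u
        self.oracle_labels_u = oracle_labels_u
        # Stage 3 of the graph-embedded criterion is Gini by definition;
        # supervised/oracle Stage 3 follows the configured impurity.
        self.stage3_impurity = "gini" if variant == "graph" else config.impurity

    def grow(self) -> TreeNode:
        uniform = np.full(self.K, 1.0 / self.K)
        return self._grow(
            np.arange(self.X_l.shape[0]),
            np.arange(self.X_u.shape[0]),
            depth=0,
            path=0,
            parent_dist=uniform,
        )

    # -- leaves ---------------------------------------------------------
    def _leaf(self, labeled_ids, unlabeled_ids, parent_dist) -> TreeNode:
        counts = np.bincount(self.y_l[labeled_ids], minlength=self.K).astype(float)
        if self.cfg.leaves_use_pseudo and self.stage3_labels_u is not None and unlabeled_ids.size:
            counts += np.bincount(self.stage3_labels_u[unlabeled_ids], minlength=self.K)
        if counts.sum() == 0:
            return TreeNode(distribution=parent_dist.copy())
        dist = (counts + 1.0) / (counts.sum() + self.K)  # Laplace smoothing
        return TreeNode(distribution=dist)

    # -- recursion ------------------------------------------------------
    def _grow(self, labeled_ids, unlabeled_ids, depth, path, parent_dist) -> TreeNode:
        y_node = self.y_l[labeled_ids]
        stop = (
            depth >= self.cfg.max_depth
            or labeled_ids.size < self.cfg.min_labeled_split
            or np.unique(y_node).size < 2
        )
        if stop:
            return self._leaf(labeled_ids, unlabeled_ids, parent_dist)

        best = self._choose_split(labeled_ids, unlabeled_ids, depth, path)
        if best is None:
            return self._leaf(labeled_ids, unlabeled_ids, parent_dist)
        split, left_l, right_l, left_u, right_u = best
        my_dist = self._leaf(labeled_ids, unlabeled_ids, parent_dist).distribution
        left = self._grow(left_l, left_u, depth + 1, 2 * path, my_dist)
        right = self._grow(right_l, right_u, depth + 1, 2 * path + 1, my_dist)
        return TreeNode(split=split, left=left, right=right)

    # -- the three stages ----------------------------------------------
    def _choose_split(self, labeled_ids, unlabeled_ids, depth, path):
        cfg = self.cfg
        d = self.X_l.shape[1]
        rng = np.random.default_rng(np.random.SeedSequence([self.tree_seed, depth, path]))
        W = generate_candidates(d, cfg.n_candidates, rng, cfg.n_nonzero, cfg.axis_fraction)

        Xl_node = self.X_l[labeled_ids]
        Xu_node = self.X_u[unlabeled_ids] if unlabeled_ids.size else np.empty((0, d))

        # Stage 2 members and labels
        if self.stage2_scope == "labeled" or not unlabeled_ids.size:
            X2 = Xl_node
            y2 = self.y_l[labeled_ids]
        else:  # all_oracle
            X2 = np.vstack([Xl_node, Xu_node])
            y2 = np.concatenate([self.y_l[labeled_ids], self.oracle_labels_u[unlabeled_ids]])
        P2 = X2 @ W.T

        taus = np.full(cfg.n_candidates, np.nan)
        for j in range(cfg.n_candidates):
            res = best_threshold(P2[:, j], y2, self.K, cfg.impurity)
            if res is not None:
                taus[j] = res[0]
        valid = ~np.isnan(taus)
        if not valid.any():
            return None

        # Stage 3: score valid candidates over the stage-3 member set
        Pl = Xl_node @ W.T
        Pu = Xu_node @ W.T if unlabeled_ids.size else np.empty((0, cfg.n_candidates))
        yl = self.y_l[labeled_ids]
        if self.stage3_scope == "labeled":
            yu = None
        elif self.stage3_scope == "all_pseudo":
            yu = self.stage3_labels_u[unlabeled_ids] if unlabeled_ids.size else None
        else:  # all_oracle
            yu = self.oracle_labels_u[unlabeled_ids] if unlabeled_ids.size else None

        gains = np.full(cfg.n_candidates, -np.inf)
        for j in np.nonzero(valid)[0]:
            tau = taus[j]
            left_counts = np.bincount(yl[Pl[:, j] < tau], minlength=self.K).astype(float)
            right_counts = np.bincount(yl[Pl[:, j] >= tau], minlength=self.K).astype(float)
            if yu is not None:
                left_counts += np.bincount(yu[Pu[:, j] < tau], minlength=self.K)
                right_counts += np.bincount(yu[Pu[:, j] >= tau], minlength=self.K)
            gains[j] = _counts_gain(left_counts, right_counts, self.stage3_impurity)
        j_best = int(np.argmax(gains))  # ties: first in generation order
        split = SplitFunction(weights=W[j_best].copy(), threshold=float(taus[j_best]))

        mask_l = Pl[:, j_best] < taus[j_best]
        left_l, right_l = labeled_ids[mask_l], labeled_ids[~mask_l]
        if unlabeled_ids.size:
            mask_u = Pu[:, j_best] < taus[j_best]
            left_u, right_u = unlabeled_ids[mask_u], unlabeled_ids[~mask_u]
        else:
            left_u = right_u = np.empty(0, dtype=int)
        # a Stage-2 threshold always separates its own members, but guard
        # against a fully one-sided routing of the complete population
        if left_l.size + left_u.size == 0 or right_l.size + right_u.size == 0:
            return None
        return split, left_l, right_l, left_u, right_u


def select_split(
    candidates: list[tuple[np.ndarray, float]],
    pop: NodePopulation,
    dataset: PartiallyLabeledDataset,
    labels: np.ndarray,
    pseudo: np.ndarray | None,
    n_classes: int,
    variant: str = "graph",
    impurity: str = "gini",
) -> SplitFunction | None:
    """Stage 3: select the best (w, tau) pair for a node population.

    ``variant="graph"`` scores each candidate with the graph-embedded
    gain (routing labeled AND pseudo-labeled members); ``"standard"``
    scores with the supervised gain over labeled members only.  Ties go
    to the first candidate in generation order.  Returns None when no
    candidate is supplied.
    """
    from .gain import graph_embedded_gain, supervised_gain

    best: SplitFunction | None = None
    best_gain = -np.inf
    for w, tau in candidates:
        sf = SplitFunction(weights=np.asarray(w, float), threshold=float(tau))
        if variant == "graph":
            g = graph_embedded_gain(pop, sf, dataset, labels, pseudo, n_classes)
        else:
            g = supervised_gain(pop, sf, dataset, labels, n_classes, impurity)
        if g > best_gain:
            best, best_gain = sf, g
    return best


def grow_tree(
    dataset: PartiallyLabeledDataset,
    config: ForestConfig,
    variant: str = "graph",
    pseudo: np.ndarray | None = None,
    seed: int = 0,
) -> TreeNode:
    """Grow a single tree on the dataset's blocks (no bootstrap)."""
    _check_variant(dataset, variant, pseudo)
    grower = _TreeGrower(
        dataset.X_labeled,
        dataset.y_labeled,
        dataset.X_unlabeled,
        dataset.n_classes,
        variant,
        config,
        tree_seed=seed,
        stage3_labels_u=pseudo,
        oracle_labels_u=dataset.y_unlabeled_oracle,
    )
    return grower.grow()


def _check_variant(dataset, variant, pseudo) -> None:
    if variant not in VARIANT_STAGES:
        raise ValueError(f"unknown variant {variant!r}")
    if variant in ORACLE_VARIANTS and dataset.n_unlabeled and dataset.y_unlabeled_oracle is None:
        raise ValueError(f"variant {variant!r} requires withheld oracle labels")
    if variant == "graph" and dataset.n_unlabeled and pseudo is None:
        raise ValueError("graph variant requires pseudo-labels for the unlabeled block")


def train_forest(
    dataset: PartiallyLabeledDataset,
    config: ForestConfig | None = None,
    variant: str = "graph",
    pseudo: np.ndarray | None = None,
) -> Forest:
    """Train a forest of ``config.n_trees`` trees.

    For the graph variant, label propagation runs ONCE over all l+u
    training points before any tree is grown and every tree reuses the
    same pseudo-labels.  The labeled block is bootstrapped per tree by
    default; the unlabeled block is shared in full.
    """
    config = config or ForestConfig()
    dataset.require_trainable()
    if variant == "graph" and dataset.n_unlabeled and pseudo is None:
        prop = propagate_dataset(
            dataset,
            n_neighbors=config.n_neighbors,
            sigma=config.sigma,
            lam=config.lam,
        )
        pseudo = prop.pseudo_labels_unlabeled
    _check_variant(dataset, variant, pseudo)

    master = np.random.SeedSequence(config.seed)
    tree_seeds = master.generate_state(config.n_trees, dtype=np.uint32) & 0x7FFFFFFF
    trees = []
    l = dataset.n_labeled
    for t in range(config.n_trees):
        tree_seed = int(tree_seeds[t])
        if config.bootstrap:
            boot_rng = np.random.default_rng(np.random.SeedSequence([tree_seed, 1_000_003]))
            boot = boot_rng.integers(0, l, size=l)
        else:
            boot = np.arange(l)
        grower = _TreeGrower(
            dataset.X_labeled[boot],
            dataset.y_labeled[boot],
            dataset.X_unlabeled,
            dataset.n_classes,
            variant,
            config,
            tree_seed=tree_seed,
            stage3_labels_u=pseudo,
            oracle_labels_u=dataset.y_unlabeled_oracle,
        )
        trees.append(grower.grow())
    return Forest(
        trees=trees,
        n_classes=dataset.n_classes,
        n_features=dataset.n_features,
        variant=variant,
        config=config,
    )


def predict(forest: Forest, X: np.ndarray) -> np.ndarray:
    """Average the per-tree leaf distributions; rows sum to 1.

    This single code path serves every variant: trained forests differ
    only in which splits were selected, never in how they are applied.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != forest.n_features:
        raise ValueError(
            f"expected (n, {forest.n_features}) query matrix, got {X.shape}"
        )
    out = np.zeros((X.shape[0], forest.n_classes))
    idx = np.arange(X.shape[0])
    for tree in forest.trees:
        _accumulate(tree, X, idx, out)
    out /= len(forest.trees)
    return out


def _accumulate(node: TreeNode, X: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
    if node.is_leaf:
        out[idx] += node.distribution
        return
    if idx.size == 0:
        return
    mask = node.split.goes_left(X[idx])
    _accumulate(node.left, X, idx[mask], out)
    _accumulate(node.right, X, idx[~mask], out)


# -- serialization ------------------------------------------------------


def _flatten_tree(root: TreeNode) -> list[dict]:
    nodes: list[dict] = []

    def visit(node: TreeNode) -> int:
        my_id = len(nodes)
        nodes.append({})
        if node.is_leaf:
            nodes[my_id] = {"kind": "leaf", "distribution": node.distribution.tolist()}
        else:
            left_id = visit(node.left)
            right_id = visit(node.right)
            nodes[my_id] = {
                "kind": "split",
                "weights": node.split.weights.tolist(),
                "threshold": node.split.threshold,
                "left": left_id,
                "right": right_id,
            }
        return my_id

    visit(root)
    return nodes


def _unflatten_tree(nodes: list[dict]) -> TreeNode:
    def build(i: int) -> TreeNode:
        spec = nodes[i]
        if spec["kind"] == "leaf":
            return TreeNode(distribution=np.asarray(spec["distribution"], float))
        return TreeNode(
            split=SplitFunction(
                weights=np.asarray(spec["weights"], float),
                threshold=float(spec["threshold"]),
            ),
            left=build(spec["left"]),
            right=build(spec["right"]),
        )

    return build(0)


def save_forest(forest: Forest, path: str | Path) -> None:
    """Serialize a forest to a self-describing JSON model file.

    Keys are written in sorted order so save -> load -> save is
    byte-stable; floats use ``repr`` and round-trip exactly.
    """
    payload = {
        "schema_version": SCHEMA_VERSION,
        "n_classes": forest.n_classes,
        "n_features": forest.n_features,
        "variant": forest.variant,
        "config": forest.config.to_dict(),
        "trees": [_flatten_tree(t) for t in forest.trees],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def load_forest(path: str | Path) -> Forest:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: truncated or invalid model file: {exc}") from exc
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"{path}: schema version {version!r} unsupported (expected {SCHEMA_VERSION})"
        )
    cfg = ForestConfig(**payload["config"])
    return Forest(
        trees=[_unflatten_tree(nodes) for nodes in payload["trees"]],
        n_classes=payload["n_classes"],
        n_features=payload["n_features"],
        variant=payload["variant"],
        config=cfg,
    )
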