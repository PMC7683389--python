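"""Forest variants and the experiment harness.

Six variants share one training code path and differ only in how node
splits are supervised:

- ``control`` / ``standard``: supervised gains from the small labeled
  set at every stage (plain random forest).
- ``perfect_stage3``: Stage 2 on the labeled set, Stage 3 scored with
  the withheld true labels of the unlabeled block — isolates how much
  accuracy is lost to biased split SELECTION alone.
- ``perfect_splitting``: withheld true labels drive Stage 2 and Stage 3.
- ``graph``: the semi-supervised method — Stage 3 scored with
  propagated pseudo-labels.
- ``optimal``: true labels of all training points supervise node
  splitting (leaves still come from the labeled set); the empirical
  upper bound for semi-supervised variants.

The harness functions run paired-seed comparisons on synthetic data and
return tidy tables (one row per variant x condition x repeat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import PartiallyLabeledDataset, split_labeled_subset
from .forest import Forest, ForestConfig, ORACLE_VARIANTS, VARIANT_STAGES, train_forest
from . import synthetic


@dataclass
class VariantSpec:
    """A named forest variant, with oracle labels where required."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in VARIANT_STAGES:
            raise ValueError(f"unknown variant {self.name!r}")

    @property
    def needs_oracle(self) -> bool:
        return self.name in ORACLE_VARIANTS


def run_variant(
    dataset: PartiallyLabeledDataset,
    variant: VariantSpec | str,
    config: ForestConfig | None = None,
) -> Forest:
    """Train one forest variant, validating its supervision requirements."""
    spec = VariantSpec(variant) if isinstance(variant, str) else variant
    if spec.needs_oracle and dataset.n_unlabeled and dataset.y_unlabeled_oracle is None:
        raise ValueError(
            f"variant {spec.name!r} requires the withheld true labels of the unlabeled block"
        )
    return train_forest(dataset, config=config, variant=spec.name)


def evaluate_accuracy(forest: Forest, X: np.ndarray, y: np.ndarray) -> float:
    """Plain classification accuracy of hard predictions."""
    return float(np.mean(forest.predict(X) == np.asarray(y)))


def accuracy_curve(
    train: PartiallyLabeledDataset,
    test: PartiallyLabeledDataset,
    variants: list[str],
    labeled_sizes: list[int],
    repeats: int,
    master_seed: int = 0,
    config: ForestConfig | None = None,
) -> pd.DataFrame:
    """Accuracy as a function of the number of labeled samples.

    For each (variant, n, repeat) cell the labeled subset is re-drawn
    with a seed derived from ``master_seed``, a forest is trained, and
    accuracy is measured on the held-out test set.  Returns a tidy table
    with columns (variant, n_labeled, repeat, accuracy).
    """
    if test.n_labeled == 0:
        raise ValueError("test set is empty")
    config = config or ForestConfig()
    ss = np.random.SeedSequence(master_seed)
    cell_seeds = ss.generate_state(len(labeled_sizes) * repeats, dtype=np.uint32) & 0x7FFFFFFF
    rows = []
    for ni, n in enumerate(labeled_sizes):
        for r in range(repeats):
            seed = int(cell_seeds[ni * repeats + r])
            subset = split_labeled_subset(train, n=n, seed=seed)
            for variant in variants:
                cfg = ForestConfig(**{**config.to_dict(), "seed": seed})
                forest = run_variant(subset, variant, cfg)
                acc = evaluate_accuracy(forest, test.X_labeled, test.y_labeled)
                rows.append(
                    {"variant": variant, "n_labeled": n, "repeat": r, "accuracy": acc}
                )
    return pd.DataFrame(rows)


def summarize_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(variant, n) mean and standard deviation of accuracy."""
    return (
        table.groupby(["variant", "n_labeled"])["accuracy"]
        .agg(["mean", "std"])
        .reset_index()
    )


def run_moons_comparison(
    n_seeds: int = 20,
    n_per_class: int = 200,
    labeled_per_class: int = 2,
    noise_scale: float = 0.05,
    n_trees: int = 25,
    variants: tuple[str, ...] = ("standard", "graph", "optimal"),
    base_seed: int = 0,
    config: ForestConfig | None = None,
) -> pd.DataFrame:
    """Paired comparison of forest variants on two-moons data.

    Each repeat draws a fresh training set (with ``labeled_per_class``
    labels kept per class) and a fresh test set, trains every variant on
    the SAME split with the SAME master seed, and records test accuracy.
    """
    base_cfg = (config or ForestConfig()).to_dict()
    base_cfg["n_trees"] = n_trees
    ss = np.random.SeedSequence([base_seed, 777])
    seeds = ss.generate_state(2 * n_seeds, dtype=np.uint32) & 0x7FFFFFFF
    rows = []
    for r in range(n_seeds):
        data_seed = int(seeds[2 * r])
        test_seed = int(seeds[2 * r + 1])
        full = synthetic.make_moons(n_per_class=n_per_class, noise_scale=noise_scale, seed=data_seed)
        train = synthetic.as_partially_labeled(full, labeled_per_class, seed=data_seed)
        test = synthetic.make_moons(n_per_class=n_per_class, noise_scale=noise_scale, seed=test_seed)
        for variant in variants:
            cfg = ForestConfig(**{**base_cfg, "seed": data_seed})
            forest = run_variant(train, variant, cfg)
            acc = evaluate_accuracy(forest, test.X_labeled, test.y_labeled)
            rows.append({"variant": variant, "repeat": r, "accuracy": acc})
    return pd.DataFrame(rows)


def run_bottleneck_experiment(
    n_seeds: int = 20,
    n_labeled: int = 20,
    n_unlabeled: int = 2000,
    n_test: int = 1000,
    dimension: int = 20,
    noise_scale: float = 0.5,
    class_separation: float = 2.0,
    n_trees: int = 25,
    impurity: str = "entropy",
    base_seed: int = 0,
) -> pd.DataFrame:
    """Bottleneck study: which stage suffers most from scarce labels?

    Three forests are grown per repeat on two embedded Gaussian
    clusters: ``control`` sees only the small labeled set S1
    (|S1| = ``n_labeled``); ``perfect_stage3`` additionally uses the
    true labels of the large set S2 (|S2| = ``n_unlabeled``) to score
    Stage 3; ``perfect_splitting`` uses S2's labels for Stages 2 and 3.
    The entropy gain is the supervised criterion.  If split SELECTION is
    the bottleneck, the control -> perfect_stage3 gap dwarfs the
    perfect_stage3 -> perfect_splitting gap.

    ``class_separation`` is the center distance in units of the noise
    standard deviation.  The default of 2 makes the classes overlap
    heavily (Bayes accuracy about 84%), emulating the hard machine
    learning benchmarks on which split-selection bias, not class
    geometry, limits accuracy; widely separated clusters leave this
    experiment without dynamic range.
    """
    ss = np.random.SeedSequence([base_seed, 1313])
    seeds = ss.generate_state(2 * n_seeds, dtype=np.uint32) & 0x7FFFFFFF
    n_per_class = (n_labeled + n_unlabeled + n_test + 1) // 2
    rows = []
    for r in range(n_seeds):
        data_seed = int(seeds[2 * r])
        part_seed = int(seeds[2 * r + 1])
        # one pooled draw so train and test share the same embedding
        full = synthetic.make_clusters(
            n_per_class=n_per_class,
            noise_scale=noise_scale,
            dimension=dimension,
            seed=data_seed,
            center_distance=class_separation * noise_scale,
        )
        train_full, test = _partition(full, n_test=n_test, seed=part_seed)
        train = split_labeled_subset(train_full, n=n_labeled, seed=data_seed)
        for variant in ("control", "perfect_stage3", "perfect_splitting"):
            cfg = ForestConfig(n_trees=n_trees, impurity=impurity, seed=data_seed)
            forest = run_variant(train, variant, cfg)
            acc = evaluate_accuracy(forest, test.X_labeled, test.y_labeled)
            rows.append({"variant": variant, "repeat": r, "accuracy": acc})
    return pd.DataFrame(rows)


def _partition(
    full: PartiallyLabeledDataset,
    n_test: int,
    seed: int,
) -> tuple[PartiallyLabeledDataset, PartiallyLabeledDataset]:
    """Random disjoint train/test partition of a fully labeled dataset."""
    rng = np.random.default_rng(seed)
    n = full.n_labeled
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]

    def sub(idx):
        return PartiallyLabeledDataset(
            X_labeled=full.X_labeled[idx],
            y_labeled=full.y_labeled[idx],
            X_unlabeled=np.empty((0, full.n_features)),
            n_classes=full.n_classes,
            label_names=full.label_names,
        )

    return sub(train_idx), sub(test_idx)


def paired_gaps(table: pd.DataFrame, first: str, second: str) -> np.ndarray:
    """Per-repeat accuracy gap ``second - first`` from a tidy table."""
    a = table[table.variant == first].sort_values("repeat")["accuracy"].to_numpy()
    b = table[table.variant == second].sort_values("repeat")["accuracy"].to_numpy()
    if a.size != b.size:
        raise ValueError("variants have different repeat counts")
    return b - a


def sign_test_pvalue(gaps: np.ndarray) -> float:
    """One-sided paired sign test that the gaps are positive (ties dropped)."""
    from scipy.stats import binomtest

    gaps = np.asarray(gaps)
    wins = int(np.sum(gaps > 0))
    informative = int(np.sum(gaps != 0))
    if informative == 0:
        return 1.0
    return float(binomtest(wins, informative, 0.5, alternative="greater").pvalue)
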