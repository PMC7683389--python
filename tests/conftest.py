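import numpy as np
import pytest

from gerforest import ForestConfig, synthetic


@pytest.fixture
def two_cluster_ssl():
    """Two well-separated 2-D Gaussian clusters, one label per cluster."""
    full = synthetic.make_clusters(n_per_class=50, noise_scale=0.5, seed=7)
    return synthetic.as_partially_labeled(full, labeled_per_class=1, seed=7)


@pytest.fixture
def moons_ssl():
    """Two moons, 2 labels per class, 200 points per class."""
    full = synthetic.make_moons(n_per_class=200, noise_scale=0.05, seed=3)
    return synthetic.as_partially_labeled(full, labeled_per_class=2, seed=3)


@pytest.fixture
def small_config():
    return ForestConfig(n_trees=5, n_candidates=20, max_depth=10, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
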