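import numpy as np
import pytest

import stsketch as sts


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """2,000-cell Xenium-like stripes dataset, default expression settings."""
    cfg = sts.SimulationConfig(
        n_locations=2000, n_genes=200, layout="random", pattern="stripes",
        n_signal_genes_per_class=20, seed=7,
    )
    return sts.make_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_dataset():
    """120-cell grid dataset for fast structural checks."""
    cfg = sts.SimulationConfig(
        n_locations=120, n_genes=30, layout="grid", pattern="stripes",
        n_classes=3, n_signal_genes_per_class=5, zero_inflation=0.0, seed=3,
    )
    return sts.make_dataset(cfg)


@pytest.fixture(scope="session")
def small_context(small_dataset):
    """Shared preprocessing context for the small dataset."""
    cfg = sts.BenchmarkConfig(min_counts=20, fractions=(0.1,), replicates=2)
    filtered, context = sts.prepare_context(small_dataset, cfg)
    return filtered, context, cfg
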