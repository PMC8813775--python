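import numpy as np
import pytest

from stagegate import (
    GenomeConfig,
    VarianceComponents,
    load_baseline,
    sample_architecture,
    simulate_founders,
)


@pytest.fixture(scope="session")
def baseline():
    return load_baseline()


@pytest.fixture(scope="session")
def small_cfg():
    """A fast 4-chromosome genome for unit tests."""
    return GenomeConfig(
        n_chromosomes=4, sites_per_chromosome=120, burn_in_generations=300, seed=11
    )


@pytest.fixture(scope="session")
def small_founders(small_cfg):
    return simulate_founders(small_cfg, 4)


@pytest.fixture(scope="session")
def default_founders():
    """Founders at the full genome defaults (18 chromosomes, 500 sites)."""
    cfg = GenomeConfig(seed=11)
    return simulate_founders(cfg, 4, min_segregating_per_chromosome=100)


@pytest.fixture(scope="session")
def small_arch(small_founders):
    founders, _ = small_founders
    rng = np.random.default_rng(5)
    return sample_architecture(founders, VarianceComponents(), 30, rng)
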