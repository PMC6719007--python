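import numpy as np
import pytest

from fetalfrac.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort for unit tests (shallow profiles, n=320)."""
    cfg = SimConfig(n_samples=320, fragments_per_sample=10_000, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def cohort2000():
    """Default-condition cohort (n=2000) used by the replication tests."""
    return simulate_dataset(SimConfig(seed=17))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def random_profiles(rng):
    """Random valid profile matrix (Dirichlet rows, N x 171)."""
    return rng.dirichlet(np.full(171, 2.0), size=60)
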