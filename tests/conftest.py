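import numpy as np
import pytest

from dmmgwas import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small continuous-phenotype cohort shared by read-only tests."""
    cfg = SimConfig(n=120, p=300, k=10, t=5, sigma_u2=5.0, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
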