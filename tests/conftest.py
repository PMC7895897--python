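import numpy as np
import pytest

from phagekit.config import DEFAULT_CONFIG
from phagekit.simulate import FixtureSpec, gen_mge_set


@pytest.fixture(scope="session")
def cfg():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def small_mge_set():
    """A reduced labeled phage/ICE set for fast classifier unit tests."""
    genomes, labels = gen_mge_set(FixtureSpec(rng_seed=11, n_phage=60, n_ice=60))
    return genomes, labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
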