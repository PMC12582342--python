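import numpy as np
import pytest
from hypothesis import settings

from proteoturn.synthetic_data import SMALL, simulate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared by I/O and pipeline tests."""
    return simulate_cohort(SMALL, seed=11)


@pytest.fixture(scope="session")
def noiseless_cohort():
    return simulate_cohort(SMALL.noiseless(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
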