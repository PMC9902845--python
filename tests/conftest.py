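import numpy as np
import pytest

from mirdpk.synthetic_data import simulate_cohort


@pytest.fixture(scope="session")
def noiseless_cohort():
    """One deterministic cohort with zero measurement noise."""
    return simulate_cohort(n=9, seed=11, cv=0.0)


@pytest.fixture(scope="session")
def noisy_cohort():
    """One deterministic cohort at the default 5% measurement CV."""
    return simulate_cohort(n=9, seed=11, cv=0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
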