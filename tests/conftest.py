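import numpy as np
import pytest

from crcclass.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=468, seed 1) shared across tests."""
    cohort, truth = generate_cohort(SyntheticConfig(), seed=1)
    return cohort, truth


@pytest.fixture(scope="session")
def default_calls(default_cohort):
    from crcclass.functional_calls import driver_profile

    cohort, _ = default_cohort
    return driver_profile(cohort)


@pytest.fixture(scope="session")
def default_profiles(default_cohort, default_calls):
    from crcclass.apc_profile import build_apc_profile

    cohort, _ = default_cohort
    by_sample = cohort.mutations_by_sample()
    return [build_apc_profile(c, by_sample[c.sample_id]) for c in default_calls]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
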