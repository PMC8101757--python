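import numpy as np
import pytest

from groovetap.synthetic_data import CohortParams, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort bundle shared across read-only tests."""
    params = CohortParams(n_pd=6, n_control=4, n_completers=4)
    return simulate_cohort(params, seed=99)
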