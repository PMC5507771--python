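import numpy as np
import pytest

from metabopredict import CohortConfig, simulate_cohort
from metabopredict.library import default_library


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (n=20, day 0 + 20, coarse grid) for fast tests."""
    cfg = CohortConfig(
        n_animals=20,
        timepoints=(0, 20),
        n_ppm_points=1500,
        group_fractions={"ob_igt": 0.05, "l_igt": 0.05, "lng": 0.10},
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One full default cohort, shared across tests that need realism."""
    return simulate_cohort(CohortConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
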