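import logging

import numpy as np
import pytest

from emergeeg.synthcohort import CohortConfig, simulate_cohort

logging.getLogger("emergeeg").setLevel(logging.WARNING)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(seed=42)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A short-duration configuration for tests where only structure matters."""
    return CohortConfig(
        emergence_duration_s=120.0,
        post_ror_s=40.0,
        induction_duration_s=120.0,
        beta_onset_mean_s={"propofol": 20.0, "sevoflurane": 60.0, "isoflurane": 60.0},
        seed=7,
    )


@pytest.fixture(scope="session")
def emergence_cohort(default_config):
    """Default-condition emergence cohort (15 subjects x 3 groups)."""
    return simulate_cohort(default_config, phase="emergence")


@pytest.fixture(scope="session")
def induction_cohort(default_config):
    """Default-condition induction cohort (15 subjects x 3 groups)."""
    return simulate_cohort(default_config, phase="induction")
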