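import numpy as np
import pytest

from synchromet.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small 3-arm cohort shared by read-only tests."""
    config = CohortConfig(n_patients_per_arm=2, lesions_per_patient=(2, 3), seed=42)
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
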