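import numpy as np
import pytest

from conwas import Cohort, generate_cohort

from tests.helpers import two_group_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_cohort() -> Cohort:
    """Two-group cohort with a strong planted effect, thresholded."""
    return generate_cohort(two_group_spec(2.0), seed=11).thresholded(0.25)


@pytest.fixture(scope="session")
def null_cohort() -> Cohort:
    """Same design with zero effect: group carries no information."""
    return generate_cohort(two_group_spec(0.0), seed=11).thresholded(0.25)
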