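import numpy as np
import pytest

from cerebroquant.config import default_config
from cerebroquant.synthetic.cohort import (
    cohort_to_long,
    cohort_to_wide,
    generate_cohort,
)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort, fixed seed."""
    return generate_cohort(default_config(seed=42))


@pytest.fixture(scope="session")
def long_df(cohort):
    return cohort_to_long(cohort)


@pytest.fixture(scope="session")
def wide_df(cohort):
    return cohort_to_wide(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
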