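import numpy as np
import pytest

from polyprisk.schema import default_schema
from polyprisk.synthetic import SyntheticSpec, generate_cohort, reference_cohort_roster


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def roster():
    return reference_cohort_roster()


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-law cohort for unit tests (300 per sex)."""
    spec = SyntheticSpec(n_male=300, n_female=300, seed=42)
    return spec, generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
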