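import numpy as np
import pytest

from hfcoi.cohort import default_cohort_config, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def default_config():
    return default_cohort_config(seed=42)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)
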