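import numpy as np
import pytest

from condsmolt.synthetic_data import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_config():
    """Two-site, full-length scenario used by several integration tests."""
    return ScenarioConfig(sites=("site_1", "site_2"), seed=7, cohort_n=100)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_scenario(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
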