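import pytest
from hypothesis import HealthCheck, settings

import csasim as cs

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return cs.GeneratorConfig(n_cells=400, n_fpus=16, n_countries=8)


@pytest.fixture(scope="session")
def world(small_config):
    return cs.generate_world(small_config, seed=11)


@pytest.fixture(scope="session")
def default_ef():
    return cs.EmissionFactors()
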