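import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from chocnv import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    return sd.SimulationConfig(n_genes=300, seed=7)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return sd.generate_annotation(small_config)
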