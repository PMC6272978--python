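import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_panel():
    """Scaled synthetic panel (153 library + 200 decoys) shared by slow tests."""
    from selectisom.synthetic import GeneratorConfig, generate_library

    return generate_library(GeneratorConfig(n_decoys=200, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
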