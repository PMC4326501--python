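import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from editkit import PipelineConfig, make_reference

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def small_refs():
    return make_reference(5, length_range=(20, 24), rng_seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
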