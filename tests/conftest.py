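import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neonoxy.autoregulation import AutoregNomogram
from neonoxy.constants import PhysioConstants

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def constants() -> PhysioConstants:
    return PhysioConstants()


@pytest.fixture(scope="session")
def nomogram() -> AutoregNomogram:
    return AutoregNomogram()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240611)
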