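import numpy as np
import pytest
from hypothesis import settings

from cylsfm import CylinderParams, make_real_switch_schedule

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> CylinderParams:
    return CylinderParams()


@pytest.fixture(scope="session")
def canonical_schedule(params):
    return make_real_switch_schedule(params, "paper")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
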