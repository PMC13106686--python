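import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hpslab as h

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return h.load_residue_params()


@pytest.fixture(scope="session")
def ff():
    return h.ForceFieldConfig()


@pytest.fixture(scope="session")
def tau_seq():
    return h.packaged_sequence("tau_2n4r")


@pytest.fixture(scope="session")
def abeta_seq():
    return h.packaged_sequence("abeta40")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
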