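import pytest
from hypothesis import settings, HealthCheck

from actidiff import load_preset

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def case1():
    return load_preset("case1_janus_nano")


@pytest.fixture(scope="session")
def case2():
    return load_preset("case2_vesicle")
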