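import pytest
from hypothesis import HealthCheck, settings

import taxonconcept as tc

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def vireo():
    return tc.build_fixture("vireo")


@pytest.fixture
def pterodroma():
    return tc.build_fixture("pterodroma")


@pytest.fixture
def poicephalus():
    return tc.build_fixture("poicephalus")
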