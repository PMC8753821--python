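import pytest
from hypothesis import HealthCheck, settings

from rbgdesign import DesignParams, plan_design

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> DesignParams:
    return DesignParams()


@pytest.fixture(scope="session")
def default_plans(default_params):
    return plan_design(default_params)


@pytest.fixture(scope="session")
def stage1(default_plans):
    return default_plans[0]
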