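import pytest

from tavicea import Arm, builtin_parameter_set, build_transition_schedule
from tavicea.analyses import base_case


@pytest.fixture(scope="session")
def base_spec():
    """Bundled base-case parameter set (read-only; copy before mutating)."""
    return builtin_parameter_set("partner2a_base")


@pytest.fixture(scope="session")
def base_result(base_spec):
    """Deterministic cohort-mode base-case comparison."""
    return base_case(base_spec)


@pytest.fixture(scope="session")
def base_schedules(base_spec):
    return {arm: build_transition_schedule(base_spec, arm) for arm in Arm}
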