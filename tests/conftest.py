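import pytest
from hypothesis import HealthCheck, settings

from aquaindex import ParameterSpec, StandardsTable, builtin_is10500

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def standards() -> StandardsTable:
    return builtin_is10500()


@pytest.fixture
def two_param_table() -> StandardsTable:
    """Toy table with ideal 0 and standards 100/200 (hand-checkable weights)."""
    return StandardsTable(
        [
            ParameterSpec("A", "mg/l", 0.0, 100.0, 100.0),
            ParameterSpec("B", "mg/l", 0.0, 200.0, 200.0),
        ]
    )
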