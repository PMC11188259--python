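import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    from iblood.fixtures import fixture_table2

    return fixture_table2()


@pytest.fixture(scope="session")
def crosstabs():
    from iblood.fixtures import fixture_line_crosstabs

    return fixture_line_crosstabs()
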