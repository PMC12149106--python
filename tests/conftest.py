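import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schema():
    from pmceval import default_schema

    return default_schema()


@pytest.fixture(scope="session")
def reference():
    from pmceval import load_reference_scores

    return load_reference_scores()
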