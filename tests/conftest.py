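import pytest
from hypothesis import HealthCheck, settings

from broilerseq import load_default_ethogram, worked_example_database

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def eth():
    return load_default_ethogram()


@pytest.fixture()
def example_db():
    """Two-broiler worked example: <{E} {W} {D}> and <{Ld} {P}>."""
    return worked_example_database()
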