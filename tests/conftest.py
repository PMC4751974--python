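import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from ccscreen import fixtures


@pytest.fixture(scope="session")
def octet():
    """The eight reference peptides forming four orthogonal heterodimers."""
    return fixtures.reference_octet()


@pytest.fixture(scope="session")
def pep(octet):
    """Reference peptides keyed by id (pep1..pep8)."""
    return {p.id: p for p in octet}


@pytest.fixture(scope="session")
def desired_pairs():
    return fixtures.DESIRED_PAIRS
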