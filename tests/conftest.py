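import pytest
from hypothesis import settings

from protospec import ElectrodeModel, fixtures

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fx():
    """Published reference parameter sets (three SBOs x three models)."""
    return fixtures()


@pytest.fixture(scope="session")
def electrode():
    """Ideal electrode: E0 = 400 mV, Nernst slope, no junction term."""
    return ElectrodeModel(e0=400.0)
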