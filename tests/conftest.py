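import pytest
from hypothesis import HealthCheck, settings

import floryfit as ff

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def asymmetric_system() -> ff.PolymerSolventSystem:
    """The N = 3, chi = 1.5 state used throughout as the canonical
    asymmetric two-phase configuration."""
    return ff.PolymerSolventSystem(N=3, chi=1.5)


@pytest.fixture(scope="session")
def oracle_pair(asymmetric_system):
    return ff.oracle_binodal(asymmetric_system)
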