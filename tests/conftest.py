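import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mhckin import default_parameters, simulate  # noqa: E402


@pytest.fixture(scope="session")
def reference():
    """(KineticParameters, HeatingParameters, SamplingDesign) reference set."""
    return default_parameters()


@pytest.fixture(scope="session")
def fine_trajectory(reference):
    """Reference trajectory on a 0.01-min output grid (shared, read-only)."""
    k, h, _ = reference
    return simulate(k, h, t_end=60.0, dt_out=0.01)
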