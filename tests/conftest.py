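import pytest
from hypothesis import HealthCheck, settings

from dmfsimoa import BeadPopulation, DeviceGeometry, DielectricStack, FluidState

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    # the shared fixtures are frozen dataclasses, safe to reuse across examples
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def stack():
    return DielectricStack(thickness=6e-6, rel_permittivity=3.1)


@pytest.fixture
def geom(stack):
    return DeviceGeometry(
        gap=190e-6, drive_width=2.2e-3, densify_minor=1.0e-3, stack=stack
    )


@pytest.fixture
def fluid():
    return FluidState(sigma=42e-3, viscosity=1e-3, k_factor=0.6)


@pytest.fixture
def beads():
    return BeadPopulation(count=5000)
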