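import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from aucbd import (  # noqa: E402
    CellGeometry,
    RunConditions,
    ScanSet,
    SimulationSettings,
    SoluteComponent,
    simulate_sample,
)
from aucbd.samples import (  # noqa: E402
    DEFAULT_GEOMETRY,
    DEFAULT_TEMPERATURE_K,
    lysozyme_like,
    sv_conditions,
    two_component_sample,
)


@pytest.fixture
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def sv_run():
    return sv_conditions()


@pytest.fixture
def small_sv_scan_set(geometry, sv_run):
    """A quick single-component SV simulation shared by several tests."""
    return simulate_sample(
        [lysozyme_like()], None, geometry, sv_run,
        SimulationSettings(n_part=200_000, n_steps=20, n_bins=100, seed=99),
    )
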