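import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from lumisphere.lut import build_lut  # noqa: E402
from lumisphere.mc_slab import BeamGeometry  # noqa: E402
from lumisphere.sphere_model import SphereGeometry  # noqa: E402


@pytest.fixture(scope="session")
def pencil_beam():
    """Pencil beam at normal incidence, no port/lateral losses."""
    return BeamGeometry(incidence_angle=0.0, beam_radius=0.0, port_radius=np.inf)


@pytest.fixture(scope="session")
def instrument_beam():
    return BeamGeometry()


@pytest.fixture(scope="session")
def sphere():
    return SphereGeometry()


@pytest.fixture(scope="session")
def small_lut(instrument_beam, sphere):
    """Coarse sphere-corrected table for unit tests (8x8 grid, 2e4 photons)."""
    mua = np.logspace(np.log10(1e-3), np.log10(0.3), 8)
    musp = np.linspace(1.0, 8.0, 8)
    return build_lut(
        mua,
        musp,
        (0.75, 1.41, 2.0),
        beam=instrument_beam,
        sphere=sphere,
        n_photons=20_000,
        seed=7,
    )
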