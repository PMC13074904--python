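import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from srrkit.montecarlo import BeamProfile, SimulationConfig
from srrkit.optics import OpticalProperties, SampleGeometry
from srrkit.synthetic import make_beam_profile

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

PIXEL_SCALE = 0.0361


@pytest.fixture(scope="session")
def small_beam() -> BeamProfile:
    """Synthetic oblique beam on a 129x129 grid (~ +/-2.3 mm)."""
    return make_beam_profile(grid_shape=(129, 129), origin=(64, 64))


@pytest.fixture(scope="session")
def medium_beam() -> BeamProfile:
    """Beam on a 257x257 grid (~ +/-4.6 mm), for radial-curve checks."""
    return make_beam_profile(grid_shape=(257, 257), origin=(128, 128))


@pytest.fixture(scope="session")
def geometry() -> SampleGeometry:
    return SampleGeometry()


@pytest.fixture
def turbid_props() -> OpticalProperties:
    """A mid-range turbid sample: mu_a=0.01, mu_s'=2 mm^-1, g=0.8, water."""
    return OpticalProperties(mu_a=0.01, mu_s_prime=2.0)


def fast_cfg(n_photons=20_000, seed=42, **kw) -> SimulationConfig:
    return SimulationConfig(n_photons=n_photons, seed=seed,
                            kill_radius=kw.pop("kill_radius", 30.0), **kw)
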