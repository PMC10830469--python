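import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fibrolat import KineticsModel, ScenarioSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_spec(nx=3, ny=3, n_tpa=2, dt=0.5, pore=1.0, record=1.0, seed=7,
              diameter=72.7, name="tiny"):
    """Minimal scenario for engine unit tests."""
    return ScenarioSpec(
        name=name, fiber_diameter=diameter, pore_size=pore, n_tpa=n_tpa,
        n_fibers=3 * nx * ny - nx - ny, grid_nx=nx, grid_ny=ny,
        time_step=dt, record_interval=record, tpa_fibrin_ratio=1e-6,
        tpa_concentration=1.0, rng_seed=seed)


def degenerate_kinetics(unbind=5.0, lysis=2.0, lysis_prob=1.0, q=1e-9,
                        diameter=72.7, koff_wait=1.0 / 0.036):
    """Point-mass kinetics: every unbind draw = `unbind`, every lysis draw
    = `lysis` (lytic with probability lysis_prob)."""
    return KineticsModel(
        fiber_diameter=diameter, forced_unbind_prob=q, koff_wait_s=koff_wait,
        unbind_time_samples=np.array([unbind]),
        lysis_time_samples=np.array([lysis]), lysis_prob=lysis_prob)
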