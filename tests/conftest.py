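import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from membranemc import SimulationParameters, build_lattice, insert_dopants

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A 6x6 lattice, cutoff disabled so every pair interacts."""
    return SimulationParameters(nx=6, ny=6, cutoff_radius=None)


@pytest.fixture
def small_state(small_params, rng):
    return build_lattice(small_params, rng)


@pytest.fixture
def doped_state(small_params, rng):
    state = build_lattice(small_params, rng)
    return insert_dopants(state, 6.0, 3.0, 1.5, rng)


def random_state(params, seed, concentration_pct=0.0, q=3.0, L=1.5):
    """Fresh random state; dopant footprint kept small so placement succeeds
    on small boxes."""
    rng = np.random.default_rng(seed)
    state = build_lattice(params, rng)
    if concentration_pct > 0:
        state = insert_dopants(state, concentration_pct, q, L, rng)
    return state
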