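import warnings

import numpy as np
import pytest

import topomap as tm

# the rate*dt warning is expected for heavy-tailed rate draws at dt = 10 ms
warnings.filterwarnings("ignore", message="rate \\* dt exceeds 1")


@pytest.fixture(scope="session")
def env_a():
    return tm.make_environment("A")


@pytest.fixture(scope="session")
def env_b():
    return tm.make_environment("B")


@pytest.fixture(scope="session")
def env_c():
    return tm.make_environment("C")


@pytest.fixture(scope="session")
def open_env():
    """2x2 m arena with no holes."""
    return tm.Environment(name="open")


@pytest.fixture(scope="session")
def short_traj(env_a):
    """One minute of exploration in environment A (seeded)."""
    return tm.generate_trajectory(env_a, 60.0, tm.TrajectoryParams(seed=3))


@pytest.fixture(scope="session")
def small_trains(env_a, short_traj):
    """Spike trains of a 25-cell ensemble along the short trajectory."""
    cells = tm.sample_ensemble(tm.EnsembleParams(N=25, f_mode=10, s_mode=0.5, seed=5), env_a)
    return tm.simulate_spikes(cells, short_traj, seed=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
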