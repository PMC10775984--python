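import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from placemaps import (
    ArenaSpec,
    RandomWalkConfig,
    SpikeTrain,
    Trajectory,
    generate_field_pool,
    simulate_place_cell,
    simulate_random_walk,
    simulate_spikes,
)


@pytest.fixture(scope="session")
def arena():
    return ArenaSpec()


@pytest.fixture(scope="session")
def traj_4min(arena):
    """A 4-minute foraging trajectory (12,000 samples at 50 Hz)."""
    return simulate_random_walk(arena, RandomWalkConfig(seed=11), 240.0)


@pytest.fixture(scope="session")
def cell_medium(arena):
    pool = generate_field_pool(arena, "medium", seed=12)
    return simulate_place_cell(arena, "medium", pool, seed=13)


@pytest.fixture(scope="session")
def spikes_4min(cell_medium, traj_4min):
    return simulate_spikes(cell_medium, traj_4min, seed=14)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_traj(x, y, arena=None, fs=0.02):
    """Hand-built trajectory from coordinate arrays."""
    arena = arena or ArenaSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return Trajectory(t=np.arange(len(x)) * fs, x=x, y=y, arena=arena)


def make_spikes(t, x, y):
    return SpikeTrain(
        spike_t=np.asarray(t, dtype=float),
        spike_x=np.asarray(x, dtype=float),
        spike_y=np.asarray(y, dtype=float),
    )
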