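"""Random-walk trajectory simulator."""

import numpy as np
import pytest

from placemaps import (
    ArenaSpec,
    MapGrid,
    RandomWalkConfig,
    clip_trajectory,
    simulate_random_walk,
)


def test_sample_count_and_spacing(arena):
    traj = simulate_random_walk(arena, RandomWalkConfig(seed=1), 120.0)
    assert traj.n_samples == 120 * 50
    assert np.allclose(np.diff(traj.t), 0.02)
    # a 1-s walk upsampled x50 gives exactly 50 samples
    short = simulate_random_walk(arena, RandomWalkConfig(seed=1), 1.0)
    assert short.n_samples == 50


def test_stays_inside_arena(arena, traj_4min):
    assert traj_4min.x.min() >= 0 and traj_4min.x.max() <= arena.width
    assert traj_4min.y.min() >= 0 and traj_4min.y.max() <= arena.height


def test_seeded_determinism(arena):
    cfg = RandomWalkConfig(seed=42)
    a = simulate_random_walk(arena, cfg, 60.0)
    b = simulate_random_walk(arena, cfg, 60.0)
    assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
    c = simulate_random_walk(arena, RandomWalkConfig(seed=43), 60.0)
    assert not np.array_equal(a.x, c.x)


def test_coverage_is_roughly_uniform(arena):
    """The occupancy-avoiding walk covers the arena evenly: the dwell-time
    coefficient of variation over interior 100 mm bins stays below 1."""
    traj = simulate_random_walk(arena, RandomWalkConfig(seed=5), 480.0)
    grid = MapGrid.for_arena(arena, 100.0)
    i, j = grid.bin_index(traj.x, traj.y)
    counts = np.zeros(grid.shape)
    np.add.at(counts, (i, j), 1.0)
    interior = counts[1:-1, 1:-1]
    assert interior.min() > 0
    assert interior.std() / interior.mean() < 1.0


def test_realistic_step_sizes(traj_4min):
    # ~1-s decision steps of mean 64 px = 320 mm (mu of the step Gaussian)
    step = np.hypot(np.diff(traj_4min.x[::50]), np.diff(traj_4min.y[::50]))
    assert 150 < np.median(step) < 500


def test_clip_prefix_and_idempotence(traj_4min):
    clipped = clip_trajectory(traj_4min, 60.0)
    assert clipped.n_samples == 3000
    assert np.array_equal(clipped.x, traj_4min.x[:3000])
    assert np.array_equal(clipped.t, traj_4min.t[:3000])
    again = clip_trajectory(clip_trajectory(traj_4min, 60.0), 60.0)
    assert np.array_equal(again.x, clipped.x)
    full = clip_trajectory(traj_4min, traj_4min.duration)
    assert np.array_equal(full.x, traj_4min.x)


def test_clip_beyond_duration_rejected(traj_4min):
    with pytest.raises(ValueError):
        clip_trajectory(traj_4min, traj_4min.duration + 1.0)


def test_invalid_inputs_rejected(arena):
    with pytest.raises(ValueError):
        simulate_random_walk(arena, RandomWalkConfig(seed=1), 0.5)
    with pytest.raises(ValueError):
        RandomWalkConfig(step_sigma=-1.0)
    with pytest.raises(ValueError):
        RandomWalkConfig(bias_mode="spiral")
    with pytest.raises(ValueError):
        RandomWalkConfig(step_mu=float("nan"))


@pytest.mark.parametrize("bias", ["goal", "thigmotaxis"])
def test_biased_walks_shift_occupancy(arena, bias):
    """Goal bias concentrates dwell near the goal; thigmotaxis near walls."""
    uni = simulate_random_walk(arena, RandomWalkConfig(seed=9), 240.0)
    biased = simulate_random_walk(arena, RandomWalkConfig(seed=9, bias_mode=bias), 240.0)
    if bias == "goal":
        goal = np.array([0.75 * arena.width, 0.5 * arena.height])
        d_uni = np.hypot(uni.x - goal[0], uni.y - goal[1]).mean()
        d_b = np.hypot(biased.x - goal[0], biased.y - goal[1]).mean()
    else:
        def wall_dist(t):
            return np.minimum.reduce(
                [t.x, arena.width - t.x, t.y, arena.height - t.y]).mean()
        d_uni, d_b = wall_dist(uni), wall_dist(biased)
    assert d_b < d_uni
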