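"""Map scoring: MISE, field detection, empty proportion."""

import numpy as np
import pytest

from placemaps import (
    ArenaSpec,
    FieldParams,
    MapGrid,
    MapParams,
    PlaceCellModel,
    RateMap,
    alt_metrics,
    detect_fields,
    empty_proportion,
    field_detect_error,
    histogram_map,
    mise,
)
from conftest import make_spikes, make_traj


def _tiny_truth(prob):
    arena = ArenaSpec(width=prob.shape[0], height=prob.shape[1])
    f = FieldParams((1.0, 1.0), 1000.0, 1000.0)
    return PlaceCellModel(fields=(f,), prob_map=prob.astype(float),
                          mean_rate=1.0, arena=arena)


def _tiny_map(rate, h=1.0):
    rate = np.asarray(rate, dtype=float)
    grid = MapGrid(x0=0.0, y0=0.0, h=h, nx=rate.shape[0], ny=rate.shape[1])
    return RateMap(grid=grid, rate=rate)


def test_mise_zero_for_proportional_maps():
    truth = _tiny_truth(np.array([[1.0, 2.0, 1.0]] * 3))
    rmap = _tiny_map(np.array([[3.0, 6.0, 3.0]] * 3))
    assert mise(rmap, truth) == 0.0


def test_mise_matches_two_loop_oracle(rng):
    p = rng.random((3, 3))
    r = rng.random((3, 3))
    truth = _tiny_truth(p)
    rmap = _tiny_map(r)
    rn = r / r.sum()
    pn = p / p.sum()
    oracle = sum((rn[i, j] - pn[i, j]) ** 2 for i in range(3) for j in range(3))
    assert np.isclose(mise(rmap, truth), oracle, atol=1e-12)


def test_mise_scale_invariant(cell_medium, traj_4min, spikes_4min):
    rmap = histogram_map(traj_4min, spikes_4min, MapParams("histogram", 50.0, 50.0))
    base = mise(rmap, cell_medium)
    scaled = RateMap(rmap.grid, rmap.rate * 7.3, rmap.method)
    assert np.isclose(mise(scaled, cell_medium), base, rtol=1e-12)


def test_mise_excludes_missing_bins():
    r = np.array([[1.0, np.nan], [2.0, np.nan]])
    truth = _tiny_truth(np.ones((2, 2)))
    v = mise(_tiny_map(r), truth)
    # computed over the two valid cells only: r normalized (1/3, 2/3), f (.5, .5)
    assert np.isclose(v, (1 / 3 - 0.5) ** 2 + (2 / 3 - 0.5) ** 2)


def test_mise_fully_missing_rejected():
    truth = _tiny_truth(np.ones((2, 2)))
    with pytest.raises(ValueError):
        mise(_tiny_map(np.full((2, 2), np.nan)), truth)


def test_mise_decreases_with_duration(cell_medium, traj_4min, spikes_4min):
    from placemaps import clip_trajectory, simulate_spikes

    short_traj = clip_trajectory(traj_4min, 60.0)
    short_spikes = simulate_spikes(cell_medium, short_traj, seed=21)
    p = MapParams("histogram", 40.0, 60.0)
    long_m = mise(histogram_map(traj_4min, spikes_4min, p), cell_medium)
    short_m = mise(histogram_map(short_traj, short_spikes, p), cell_medium)
    assert long_m < short_m


def _bump(shape, cx, cy, sigma, amp=1.0):
    X, Y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return amp * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sigma**2))


def test_detect_fields_cases():
    # one clear Gaussian bump covering >> 3600 mm^2 at 1 mm resolution
    surf = _bump((300, 300), 150, 150, 40)
    assert detect_fields(surf, bin_area=1.0) == 1
    assert detect_fields(np.zeros((50, 50)), bin_area=1.0) == 0
    # two disjoint plateaus of 2500 mm^2 each: below the 3600 mm^2 cutoff
    plat = np.zeros((200, 200))
    plat[10:60, 10:60] = 1.0  # 50 x 50 mm
    plat[120:170, 120:170] = 1.0
    assert detect_fields(plat, bin_area=1.0) == 0
    # scaling the surface does not change the count
    assert detect_fields(surf * 123.0, bin_area=1.0) == detect_fields(surf)


def test_detect_fields_respects_bin_area():
    # a 2x2-bin region at 40 mm bins covers 6400 mm^2 > 3600
    surf = np.zeros((10, 10))
    surf[4:6, 4:6] = 1.0
    assert detect_fields(surf, bin_area=1600.0) == 1
    assert detect_fields(surf, bin_area=400.0) == 0  # 1600 mm^2 region


def test_detect_fields_missing_below_threshold():
    surf = _bump((300, 300), 150, 150, 40)
    surf[0:5, 0:5] = np.nan
    assert detect_fields(surf, bin_area=1.0) == 1
    with pytest.raises(ValueError):
        detect_fields(np.full((4, 4), np.nan))


def test_field_detect_error_arithmetic():
    truth_surf = np.maximum(_bump((400, 400), 100, 100, 30),
                            _bump((400, 400), 300, 300, 30))
    truth = _tiny_truth(truth_surf)
    blob = _tiny_map(_bump((400, 400), 200, 200, 80))
    assert field_detect_error(blob, truth) == 1
    same = _tiny_map(truth_surf)
    assert field_detect_error(same, truth) == 0


def test_empty_proportion():
    r = np.ones((4, 4))
    assert empty_proportion(_tiny_map(r)) == 0.0
    r[:2, :] = np.nan
    assert empty_proportion(_tiny_map(r)) == 0.5


def test_sparse_unsmoothed_map_mostly_empty(arena, rng):
    # 4-minute session at 5 mm bins with no smoothing: most bins unvisited
    n = 12_000
    x = rng.uniform(0, 1200, n)
    y = rng.uniform(0, 1200, n)
    traj = make_traj(x, y, arena)
    spikes = make_spikes([0.0], [x[0]], [y[0]])
    rmap = histogram_map(traj, spikes, MapParams("histogram", 5.0, 0.0,
                                                 smooth_stage="none"))
    assert empty_proportion(rmap) > 0.5


def test_alt_metrics():
    truth = _tiny_truth(np.array([[1.0, 2.0], [3.0, 4.0]]))
    same = _tiny_map(np.array([[1.0, 2.0], [3.0, 4.0]]))
    r, d = alt_metrics(same, truth)
    assert np.isclose(r, 1.0) and np.isclose(d, 0.0)
    anti = _tiny_map(np.array([[4.0, 3.0], [2.0, 1.0]]))
    r, _ = alt_metrics(anti, truth)
    assert np.isclose(r, -1.0)
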