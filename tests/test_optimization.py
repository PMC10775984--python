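"""Pareto extraction, balanced selection and parameter regressions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placemaps import (
    fit_parameter_regression,
    pareto_front,
    predict_parameters,
    select_balanced,
    sweep,
)


def _oracle_front(obj):
    keep = []
    for i in range(len(obj)):
        dominated = False
        for j in range(len(obj)):
            if i != j and np.all(obj[j] <= obj[i]) and np.any(obj[j] < obj[i]):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return np.array(keep)


def test_trivial_fronts():
    assert np.array_equal(pareto_front(np.array([[1.0, 2.0, 3.0, 4.0]])), [0])
    two = np.array([[1.0, 1.0, 1.0, 1.0], [2.0, 2.0, 2.0, 2.0]])
    assert np.array_equal(pareto_front(two), [0])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_front_matches_pairwise_domination_oracle(seed):
    rng = np.random.default_rng(seed)
    obj = rng.random((50, 4))
    assert np.array_equal(pareto_front(obj), _oracle_front(obj))


def test_front_ignores_nan_rows():
    obj = np.array([[1.0, 1.0], [np.nan, 0.0], [2.0, 0.5]])
    assert np.array_equal(pareto_front(obj), [0, 2])


def test_select_balanced():
    assert select_balanced(np.array([[3.0, 9.0]])) == 0
    # a member achieving both minima is chosen with distance 0
    front = np.array([[1.0, 5.0], [1.0, 1.0], [4.0, 1.5]])
    assert select_balanced(front) == 1
    # tie at equal distance breaks toward smaller MISE
    tie = np.array([[0.0, 1.0], [1.0, 0.0]])
    assert select_balanced(tie) == 0


def test_balanced_never_dominated_on_both(rng):
    obj = rng.random((40, 4))
    idx = pareto_front(obj)
    k = select_balanced(obj[idx])
    chosen = obj[idx][k]
    for row in obj[idx]:
        assert not (row[0] < chosen[0] and row[1] < chosen[1])


def test_regression_recovers_exact_plane():
    r = np.array([126.0, 179.0, 253.0] * 3)
    d = np.repeat([4.0, 16.0, 64.0], 3)
    b = 22.229 + 0.115 * r - 0.413 * d
    s = 9.9 + 0.278 * r - 0.617 * d
    fit = fit_parameter_regression(r, d, b, s)
    assert np.allclose(fit.bin_coef, (22.229, 0.115, -0.413), atol=1e-9)
    assert np.allclose(fit.smooth_coef, (9.9, 0.278, -0.617), atol=1e-9)
    assert np.allclose(fit.predict(179.0, 16.0), (36.206, 49.790), atol=1e-9)


def test_regression_matches_normal_equations(rng):
    r = rng.uniform(100, 300, 9)
    d = rng.uniform(4, 64, 9)
    b = rng.uniform(10, 100, 9)
    s = rng.uniform(0, 50, 9)
    fit = fit_parameter_regression(r, d, b, s)
    X = np.column_stack([np.ones(9), r, d])
    oracle = np.linalg.solve(X.T @ X, X.T @ b)
    assert np.allclose(fit.bin_coef, oracle, atol=1e-8)


def test_regression_input_validation():
    with pytest.raises(ValueError):
        fit_parameter_regression([1, 2, 3], [1, 2, 3], [1, 2, 3], [1, 2, 3])
    r = np.ones(8)  # r constant -> rank deficient
    with pytest.raises(ValueError):
        fit_parameter_regression(r, np.arange(8), np.arange(8), np.arange(8))


def test_predict_parameters_plug_in():
    b, s = predict_parameters("histogram", "balanced", 179.0, 16.0)
    assert np.isclose(b, 36.206, atol=1e-6)
    assert np.isclose(s, 9.9 + 0.278 * 179 - 0.617 * 16, atol=1e-6)
    # "smallest available" rows return the caller's minimum bin size
    b, _ = predict_parameters("ksde", "min_error", 179.0, 16.0, min_bin_size=12.5)
    assert b == 12.5
    b, _ = predict_parameters("histogram", "min_error", 200.0, 8.0, min_bin_size=5.0)
    assert b == 5.0
    with pytest.raises(ValueError):
        predict_parameters("histogram", "balanced", -1.0, 16.0)


def test_sweep_single_combination(cell_medium, traj_4min, spikes_4min):
    res = sweep("histogram", [(cell_medium, spikes_4min)], [traj_4min],
                bin_sizes=[50.0], smoothings=[50.0])
    assert res.mise.shape == (1, 1)
    assert np.isfinite(res.mise[0, 0])
    assert res.min_error_combination() == (50.0, 50.0)
    df = res.to_dataframe()
    assert list(df["bin_size"]) == [50.0]
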