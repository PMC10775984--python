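"""Ripley's K field-size estimation and bin-size rules of thumb."""

import numpy as np
import pytest

from placemaps import (
    ArenaSpec,
    estimate_field_radius,
    fd_bins,
    ripley_h,
    sturges_bins,
)


def test_identities_hold(rng):
    pts = rng.uniform(0, 1200, (200, 2))
    radii = np.linspace(5, 600, 64)
    c = ripley_h(pts, radii)
    assert np.allclose(c.L, np.sqrt(c.K / np.pi))
    assert np.allclose(c.H, c.L - radii)
    assert np.all(c.K >= 0)


def test_csr_has_near_zero_h(rng):
    # homogeneous Poisson points: K ~ pi r^2, so H ~ 0.  Without edge
    # correction H acquires a negative bias growing with r, so check radii
    # small relative to the arena.
    pts = rng.uniform(0, 1200, (2000, 2))
    radii = np.linspace(20, 100, 20)
    c = ripley_h(pts, radii)
    assert np.max(np.abs(c.H)) < 10.0


def test_collinear_points_hand_count():
    pts = np.array([[100.0, 600.0], [200.0, 600.0], [300.0, 600.0]])
    c = ripley_h(pts, np.array([150.0]))
    lam = 3 / (1200.0 * 1200.0)
    # neighbor counts within 150: 1 + 2 + 1 = 4; K = (4/3)/lambda
    assert np.isclose(c.K[0], (4 / 3) / lam)


def test_matches_pair_count_oracle(rng):
    pts = rng.uniform(0, 1200, (400, 2))
    radii = np.array([50.0, 150.0, 400.0])
    c = ripley_h(pts, radii)
    lam = 400 / 1200.0**2
    d = np.hypot(pts[:, 0, None] - pts[None, :, 0],
                 pts[:, 1, None] - pts[None, :, 1])
    for k, r in enumerate(radii):
        count = ((d <= r).sum() - 400)  # exclude self-pairs
        assert np.isclose(c.K[k], count / 400 / lam)


def test_single_cluster_radius_recovered(rng):
    # isotropic Gaussian cluster with 2-SD radius rho
    rho = 150.0
    pts = rng.normal(600.0, rho / 2, (500, 2))
    est = estimate_field_radius(pts)
    assert 0.5 * rho <= est <= 1.5 * rho


def test_scale_equivariance(rng):
    pts = rng.normal(300.0, 60.0, (300, 2))
    small = ArenaSpec(width=600, height=600)
    big = ArenaSpec(width=1200, height=1200)
    radii = np.linspace(5.0, 300.0, 64)
    a = estimate_field_radius(pts, small, radii=radii)
    b = estimate_field_radius(pts * 2.0, big, radii=2.0 * radii)
    assert np.isclose(b, 2.0 * a, rtol=1e-12)


def test_too_few_points_rejected():
    with pytest.raises(ValueError):
        ripley_h(np.array([[1.0, 1.0]]), np.array([10.0]))


def test_sturges_printed_values():
    # 16 and 64 minutes at 50 Hz in a 1200 mm arena
    assert sturges_bins(16 * 60 * 50) == 70.0
    assert sturges_bins(64 * 60 * 50) == 63.0
    assert sturges_bins(1) == 1200.0


def test_sturges_monotone_non_increasing():
    sizes = [sturges_bins(n) for n in (10, 100, 1000, 10_000, 100_000, 1_000_000)]
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))
    with pytest.raises(ValueError):
        sturges_bins(0)


def test_fd_uniform_closed_form(rng):
    # IQR of U(0, 1200) is 600: width = 2*600*N^(-1/3) ~ 33 mm at N = 48000
    n = 48_000
    x = (np.arange(n) + 0.5) / n * 1200.0  # exact uniform quantiles
    w = 2 * 600.0 * n ** (-1 / 3)
    assert abs(fd_bins(x, x, "per_axis") - w) < 0.1
    assert round(w) == 33


def test_fd_scale_equivariance(rng):
    x = rng.uniform(0, 1200, 5000)
    y = rng.uniform(0, 1200, 5000)
    a = fd_bins(x, y, "per_axis")
    assert np.isclose(fd_bins(3 * x, 3 * y, "per_axis"), 3 * a, rtol=1e-12)
    l2 = fd_bins(x, y, "l2_norm")
    assert l2 > 0


def test_fd_zero_iqr_rejected():
    x = np.full(100, 5.0)
    with pytest.raises(ValueError):
        fd_bins(x, x, "per_axis")
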