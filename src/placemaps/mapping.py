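"""The six firing-rate map estimators.

All estimators return a :class:`RateMap`: a regular grid of firing rates in
Hz with ``NaN`` marking unvisited / undefined bins (0 means visited and
silent).  Methods:

``histogram``
    Spike map / dwell map ratio with optional Gaussian smoothing applied to
    the count maps before the division (default), to the rate map after the
    division (missing-value aware), or not at all.
``ash``
    Bivariate averaged shifted histogram with the quartic (biweight) kernel;
    the spike and dwell ASHs are built on a sub-bin grid of side h/m and
    divided.
``adaptive_smooth``
    Per-bin radius expansion until the Skaggs-McNaughton criterion
    ``r >= alpha / (n_p * sqrt(n_s))`` (r in bin widths) is met; rate is the
    enclosed spike/dwell ratio.  Pixelwise (true point distances) and
    convolution (circular unity-gain kernels on binned maps) variants.
``adaptive_bin``
    Per-bin radius expansion until at least ``t`` seconds of dwell are
    enclosed; same two variants.
``ksde``
    Ratio of Gaussian kernel density sums over spikes and positions, with
    reflection boundary correction and a 50 mm empty cutoff.
``tksde``
    Gaussian-distance-weighted average of the Blackman-smoothed
    instantaneous firing rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import fft as sfft
from scipy.spatial import cKDTree

from .grid import MapGrid, bin_data
from .smoothing import gaussian_smooth, nan_aware_smooth
from .spiking import SpikeTrain
from .walk import Trajectory

__all__ = [
    "MapParams",
    "RateMap",
    "histogram_map",
    "ash_map",
    "adaptive_smooth_map",
    "adaptive_bin_map",
    "ksde_map",
    "instantaneous_rate",
    "tksde_map",
    "make_map",
    "METHODS",
]

METHODS = ("histogram", "ash", "adaptive_smooth", "adaptive_bin", "ksde", "tksde")

#: tested parameter ranges per method: (bin range, smoothing range)
PARAM_RANGES: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "histogram": ((1.0, 640.0), (0.0, 640.0)),
    "ash": ((1.0, 640.0), (2.0, 64.0)),
    "adaptive_smooth": ((1.0, 640.0), (100.0, 32000.0)),
    "adaptive_bin": ((1.0, 640.0), (0.5, 10.0)),
    "ksde": ((2.5, 640.0), (10.0, 320.0)),
    "tksde": ((2.5, 640.0), (10.0, 640.0)),
}


@dataclass(frozen=True)
class MapParams:
    """Method selection plus the per-method bin size and smoothing value.

    ``smoothing`` is the Gaussian sigma in mm (histogram), the integer m
    (ash), alpha (adaptive_smooth), t in seconds (adaptive_bin), the kernel
    bandwidth in mm (ksde) or the spatial sigma in mm (tksde).
    """

    method: str
    bin_size: float
    smoothing: float = 0.0
    smooth_stage: str = "before_division"  # before_division | after_division | none
    padding: str = "zero"  # zero | reflect | symmetric
    empty_cutoff: float = 50.0  # mm, KSDE/tKSDE empty rule
    temporal_window: float = 0.125  # s, tKSDE instantaneous-rate window
    n_radii: int = 32
    max_radius: float = 640.0  # mm, adaptive search ceiling
    # Skaggs-McNaughton criterion exponents: r >= alpha / (n_p**p * n_s**q)
    criterion_exponents: tuple[float, float] = (1.0, 0.5)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.smooth_stage not in ("before_division", "after_division", "none"):
            raise ValueError(f"unknown smooth_stage {self.smooth_stage!r}")


@dataclass(frozen=True)
class RateMap:
    """A firing-rate map: Hz per bin, NaN where undefined."""

    grid: MapGrid
    rate: np.ndarray  # Hz, shape grid.shape, NaN = missing
    method: str = ""
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        finite = self.rate[~np.isnan(self.rate)]
        if finite.size and (np.any(~np.isfinite(finite)) or np.any(finite < 0)):
            raise ValueError("rates must be finite and non-negative where not missing")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.rate).sum())


def _adaptive_radii(params: MapParams) -> np.ndarray:
    """Linearly spaced search radii from one bin width to the ceiling."""
    return np.linspace(params.bin_size, params.max_radius, params.n_radii)


# ---------------------------------------------------------------------------
# histogram

def histogram_map(traj: Trajectory, spikes: SpikeTrain, params: MapParams) -> RateMap:
    """Bivariate histogram rate map (spike map / dwell map)."""
    grid = MapGrid.for_arena(traj.arena, params.bin_size)
    dwell, spike = bin_data(traj, spikes, grid)
    if dwell.total <= 0:
        raise ValueError("zero total dwell time")
    sigma_bins = params.smoothing / params.bin_size
    d = dwell.values
    s = spike.values
    if params.smooth_stage == "before_division" and params.smoothing > 0:
        d = gaussian_smooth(d, sigma_bins, params.padding)
        s = gaussian_smooth(s, sigma_bins, params.padding)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = s / d
    # threshold slightly above zero: FFT smoothing of large kernels leaves
    # round-off dust in truly unvisited regions
    rate[d <= 1e-10] = np.nan
    if params.smooth_stage == "after_division" and params.smoothing > 0:
        rate = nan_aware_smooth(rate, sigma_bins, params.padding)
    rate = np.where(np.isnan(rate), np.nan, np.maximum(rate, 0.0))
    return RateMap(grid, rate, "histogram", {"bin_size": params.bin_size,
                                             "sigma": params.smoothing,
                                             "smooth_stage": params.smooth_stage})


# ---------------------------------------------------------------------------
# averaged shifted histogram

def quartic_kernel(t: np.ndarray | float) -> np.ndarray | float:
    """The quartic (biweight) kernel (15/16)(1 - t^2)^2 on |t| <= 1."""
    t = np.asarray(t, dtype=float)
    out = np.where(np.abs(t) <= 1.0, (15.0 / 16.0) * (1.0 - t**2) ** 2, 0.0)
    return out if out.ndim else float(out)


def _ash_weights(m: int) -> np.ndarray:
    """ASH weight vector w(i), i = 1-m .. m-1, summing to m."""
    i = np.arange(1 - m, m)
    k = quartic_kernel(i / m)
    return m * k / k.sum()


def ash_map(traj: Trajectory, spikes: SpikeTrain, params: MapParams) -> RateMap:
    """Bivariate averaged shifted histogram rate map.

    Output resolution is ``delta = bin_size / m``, m times finer than the
    nominal bin per axis.
    """
    m = params.smoothing
    if m != int(m) or int(m) < 1:
        raise ValueError("ASH smoothing m must be a positive integer")
    m = int(m)
    arena = traj.arena
    coarse = MapGrid.for_arena(arena, params.bin_size)
    delta = params.bin_size / m
    grid = MapGrid(x0=coarse.x0, y0=coarse.y0, h=delta,
                   nx=coarse.nx * m, ny=coarse.ny * m)
    dwell, spike = bin_data(traj, spikes, grid)
    fs = arena.sample_interval
    w = _ash_weights(m) / m  # unit-sum per axis: conserves counts
    from scipy.ndimage import convolve1d

    def smooth(v: np.ndarray) -> np.ndarray:
        v = convolve1d(v, w, axis=0, mode="constant", cval=0.0)
        return convolve1d(v, w, axis=1, mode="constant", cval=0.0)

    d = smooth(dwell.values / fs)  # position counts
    s = smooth(spike.values)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = s / (d * fs)
    rate[d <= 0] = np.nan
    return RateMap(grid, rate, "ash", {"bin_size": params.bin_size, "m": m})


# ---------------------------------------------------------------------------
# adaptive methods

def _disc_offsets(r_bins: float) -> np.ndarray:
    """Binary disc kernel: 1 where the bin-center offset is within r_bins."""
    half = int(math.floor(r_bins))
    ax = np.arange(-half, half + 1)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    return (np.hypot(X, Y) <= r_bins).astype(float)


def _disc_count_stack(values: np.ndarray, h: float, radii: np.ndarray) -> np.ndarray:
    """Counts within each radius of every bin center, by FFT convolution.

    The map is zero-padded; the map FFT is computed once and reused for all
    disc kernels.
    """
    nx, ny = values.shape
    half_max = int(math.floor(radii.max() / h))
    fx = sfft.next_fast_len(nx + 2 * half_max)
    fy = sfft.next_fast_len(ny + 2 * half_max)
    F = sfft.rfft2(values, s=(fx, fy))
    out = np.empty((len(radii), nx, ny))
    for k, r in enumerate(radii):
        disc = _disc_offsets(r / h)
        half = disc.shape[0] // 2
        Kf = sfft.rfft2(disc, s=(fx, fy))
        conv = sfft.irfft2(F * Kf, s=(fx, fy))
        out[k] = conv[half:half + nx, half:half + ny]
    # FFT round-off can leave tiny negatives on exact zeros
    np.maximum(out, 0.0, out=out)
    return np.rint(out) if float(values.sum()) == float(np.rint(values.sum())) else out


def _point_count_stack(
    centers: np.ndarray, points: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Counts of ``points`` within each radius of each center (true distances)."""
    out = np.zeros((len(radii), len(centers)))
    if len(points) == 0:
        return out
    tree = cKDTree(points)
    for k, r in enumerate(radii):
        out[k] = tree.query_ball_point(centers, r, return_length=True)
    return out


def _adaptive_counts(
    traj: Trajectory,
    spikes: SpikeTrain,
    grid: MapGrid,
    radii: np.ndarray,
    impl: str,
) -> tuple[np.ndarray, np.ndarray]:
    """(n_radii, nx, ny) stacks of position and spike counts per radius."""
    if impl == "convolution":
        dwell, spike = bin_data(traj, spikes, grid)
        fs = traj.arena.sample_interval
        n_p = _disc_count_stack(dwell.values / fs, grid.h, radii)
        n_s = _disc_count_stack(spike.values, grid.h, radii)
    elif impl == "pixelwise":
        centers = grid.center_points()
        n_p = _point_count_stack(centers, traj.positions(), radii)
        n_s = _point_count_stack(centers, spikes.positions(), radii)
        n_p = n_p.reshape(-1, grid.nx, grid.ny)
        n_s = n_s.reshape(-1, grid.nx, grid.ny)
    else:
        raise ValueError(f"unknown impl {impl!r}")
    return n_p, n_s


def _first_radius_rate(
    satisfied: np.ndarray, n_p: np.ndarray, n_s: np.ndarray, fs: float
) -> np.ndarray:
    """Rate n_s/(n_p*fs) at the first satisfied radius, NaN where never met."""
    any_ok = satisfied.any(axis=0)
    first = satisfied.argmax(axis=0)  # 0 where never satisfied, masked below
    ii, jj = np.indices(first.shape)
    np_sel = n_p[first, ii, jj]
    ns_sel = n_s[first, ii, jj]
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = ns_sel / (np_sel * fs)
    rate[~any_ok] = np.nan
    return rate


def adaptive_smooth_map(
    traj: Trajectory,
    spikes: SpikeTrain,
    params: MapParams,
    impl: str = "convolution",
) -> RateMap:
    """Adaptive-smoothing (Skaggs-McNaughton) rate map.

    Around each bin the radius grows through ``n_radii`` linearly spaced
    values until ``r >= alpha / (n_p * sqrt(n_s))`` with r in bin widths;
    bins never satisfying the criterion within the ceiling are missing.
    """
    grid = MapGrid.for_arena(traj.arena, params.bin_size)
    radii = _adaptive_radii(params)
    n_p, n_s = _adaptive_counts(traj, spikes, grid, radii, impl)
    alpha = params.smoothing
    p, q = params.criterion_exponents
    r_bins = (radii / params.bin_size)[:, None, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        threshold = alpha / (n_p**p * n_s**q)
    satisfied = (n_p > 0) & (n_s > 0) & (r_bins >= threshold)
    rate = _first_radius_rate(satisfied, n_p, n_s, traj.arena.sample_interval)
    return RateMap(grid, rate, "adaptive_smooth",
                   {"bin_size": params.bin_size, "alpha": alpha, "impl": impl})


def adaptive_bin_map(
    traj: Trajectory,
    spikes: SpikeTrain,
    params: MapParams,
    impl: str = "convolution",
) -> RateMap:
    """Adaptive-binning rate map (dwell-content criterion).

    The radius grows until at least ``t = params.smoothing`` seconds of
    dwell are enclosed; the rate is the enclosed spike/dwell ratio.
    """
    import warnings

    t = params.smoothing
    if t <= 0:
        raise ValueError("adaptive_bin dwell content t must be positive")
    fs = traj.arena.sample_interval
    if traj.n_samples * fs < t:
        warnings.warn("session shorter than the dwell criterion; all bins missing",
                      stacklevel=2)
    grid = MapGrid.for_arena(traj.arena, params.bin_size)
    radii = _adaptive_radii(params)
    n_p, n_s = _adaptive_counts(traj, spikes, grid, radii, impl)
    satisfied = n_p * fs >= t
    rate = _first_radius_rate(satisfied, n_p, n_s, fs)
    return RateMap(grid, rate, "adaptive_bin",
                   {"bin_size": params.bin_size, "t": t, "impl": impl})


# ---------------------------------------------------------------------------
# KSDE

def _reflected(points: np.ndarray, arena, margin: float) -> np.ndarray:
    """Data augmented with reflections across the four arena walls.

    Only points within ``margin`` of a wall contribute a reflection.
    """
    out = [points]
    W, H = arena.width, arena.height
    x, y = points[:, 0], points[:, 1]
    for sel, refl in (
        (x <= margin, lambda p: np.column_stack([-p[:, 0], p[:, 1]])),
        (x >= W - margin, lambda p: np.column_stack([2 * W - p[:, 0], p[:, 1]])),
        (y <= margin, lambda p: np.column_stack([p[:, 0], -p[:, 1]])),
        (y >= H - margin, lambda p: np.column_stack([p[:, 0], 2 * H - p[:, 1]])),
    ):
        if sel.any():
            out.append(refl(points[sel]))
    return np.concatenate(out, axis=0)


def _gaussian_sum(query: np.ndarray, data: np.ndarray, h: float,
                  weights: np.ndarray | None = None,
                  chunk: int = 256) -> np.ndarray:
    """Sum over data of exp(-d^2 / 2h^2), optionally weighted, chunked.

    Squared distances come from the |q|^2 + |x|^2 - 2 q.x expansion so the
    inner loop is a single BLAS matmul plus one exp per pair.
    """
    out = np.empty(len(query))
    inv = 1.0 / (2.0 * h * h)
    x2 = (data**2).sum(axis=1)
    for a in range(0, len(query), chunk):
        q = query[a:a + chunk]
        d2 = (q**2).sum(axis=1)[:, None] + x2[None, :] - 2.0 * (q @ data.T)
        k = np.exp(-np.maximum(d2, 0.0) * inv)
        out[a:a + chunk] = k @ weights if weights is not None else k.sum(axis=1)
    return out


def _gaussian_sum_pair(query: np.ndarray, data: np.ndarray, h: float,
                       weights: np.ndarray, chunk: int = 256
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(plain sum, weighted sum) of the Gaussian kernel in one pass."""
    plain = np.empty(len(query))
    weighted = np.empty(len(query))
    inv = 1.0 / (2.0 * h * h)
    x2 = (data**2).sum(axis=1)
    for a in range(0, len(query), chunk):
        q = query[a:a + chunk]
        d2 = (q**2).sum(axis=1)[:, None] + x2[None, :] - 2.0 * (q @ data.T)
        k = np.exp(-np.maximum(d2, 0.0) * inv)
        plain[a:a + chunk] = k.sum(axis=1)
        weighted[a:a + chunk] = k @ weights
    return plain, weighted


def ksde_map(
    traj: Trajectory,
    spikes: SpikeTrain,
    params: MapParams,
    impl: str = "ratio_kernel",
) -> RateMap:
    """Kernel-smoothed density estimate rate map.

    At each query point the rate is the ratio of the Gaussian kernel sum
    over spike positions to that over position samples times f_s, with
    reflection boundary correction.  Query points farther than
    ``empty_cutoff`` from any position sample are missing.  ``impl`` selects
    the dense chunked evaluation (``ratio_kernel``) or a tree-truncated
    evaluation (``native``); the two agree to numerical precision.
    """
    h = params.smoothing
    if h <= 0:
        raise ValueError("KSDE bandwidth must be positive")
    arena = traj.arena
    grid = MapGrid.for_arena(arena, params.bin_size)
    query = grid.center_points()
    fs = arena.sample_interval
    margin = 6.0 * h
    pos = _reflected(traj.positions(), arena, margin)
    spk_pts = spikes.positions()
    spk = _reflected(spk_pts, arena, margin) if len(spk_pts) else spk_pts

    if impl == "ratio_kernel":
        pos_sum = _gaussian_sum(query, pos, h)
        spk_sum = _gaussian_sum(query, spk, h) if len(spk) else np.zeros(len(query))
    elif impl == "native":
        pos_sum = _truncated_gaussian_sum(query, pos, h)
        spk_sum = _truncated_gaussian_sum(query, spk, h) if len(spk) else np.zeros(len(query))
    else:
        raise ValueError(f"unknown impl {impl!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        rate = spk_sum / (pos_sum * fs)
    rate[pos_sum <= 0] = np.nan
    # empty rule: distance to the nearest *real* position sample
    tree = cKDTree(traj.positions())
    dist, _ = tree.query(query, k=1)
    rate[dist > params.empty_cutoff] = np.nan
    rate = rate.reshape(grid.shape)
    return RateMap(grid, rate, "ksde",
                   {"bin_size": params.bin_size, "bandwidth": h, "impl": impl})


def _truncated_gaussian_sum(query: np.ndarray, data: np.ndarray, h: float,
                            cutoff: float = 8.0) -> np.ndarray:
    """Gaussian kernel sums truncated at ``cutoff`` sigma via a KD-tree."""
    qt = cKDTree(query)
    dt = cKDTree(data)
    out = np.zeros(len(query))
    inv = 1.0 / (2.0 * h * h)
    pairs = qt.query_ball_tree(dt, r=cutoff * h)
    for qi, neigh in enumerate(pairs):
        if neigh:
            d2 = ((data[neigh] - query[qi]) ** 2).sum(axis=1)
            out[qi] = np.exp(-d2 * inv).sum()
    return out


# ---------------------------------------------------------------------------
# temporal KSDE

def instantaneous_rate(traj: Trajectory, spikes: SpikeTrain, window: float) -> np.ndarray:
    """Per-sample firing rate (Hz) from a Blackman-smoothed spike train.

    Spikes are assigned to the nearest position sample in time; the count
    series is convolved with a unit-gain Blackman window whose length is
    ``window * sample_rate`` rounded to the nearest odd sample count, then
    divided by the sampling interval.
    """
    fs = traj.arena.sample_interval
    if window < fs:
        raise ValueError("window must be at least one sample interval")
    n = traj.n_samples
    counts = np.zeros(n)
    if spikes.n_spikes:
        idx = np.clip(np.rint(spikes.spike_t / fs).astype(int), 0, n - 1)
        np.add.at(counts, idx, 1.0)
    w_samples = window * traj.arena.sample_rate
    k = 2 * int(round((w_samples - 1) / 2.0)) + 1
    if k <= 1:
        return counts / fs
    win = np.blackman(k)
    win /= win.sum()  # unit gain at zero frequency
    # same-length convolution regardless of n vs window length
    return np.convolve(counts, win, mode="full")[k // 2:k // 2 + n] / fs


def tksde_map(traj: Trajectory, spikes: SpikeTrain, params: MapParams) -> RateMap:
    """Temporal KSDE: spatial Gaussian average of the instantaneous rate."""
    sigma = params.smoothing
    if sigma <= 0:
        raise ValueError("tKSDE spatial sigma must be positive")
    rate_series = instantaneous_rate(traj, spikes, params.temporal_window)
    grid = MapGrid.for_arena(traj.arena, params.bin_size)
    query = grid.center_points()
    pos = traj.positions()
    den, num = _gaussian_sum_pair(query, pos, sigma, rate_series)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = num / den
    rate[den <= 0] = np.nan
    tree = cKDTree(pos)
    dist, _ = tree.query(query, k=1)
    rate[dist > params.empty_cutoff] = np.nan
    rate = rate.reshape(grid.shape)
    return RateMap(grid, rate, "tksde",
                   {"bin_size": params.bin_size, "sigma": sigma,
                    "window": params.temporal_window})


# ---------------------------------------------------------------------------

_DISPATCH = {
    "histogram": histogram_map,
    "ash": ash_map,
    "ksde": ksde_map,
    "tksde": tksde_map,
}


def make_map(
    traj: Trajectory,
    spikes: SpikeTrain,
    params: MapParams,
    impl: str | None = None,
) -> RateMap:
    """Build a rate map with the method named in ``params``."""
    if params.method == "adaptive_smooth":
        return adaptive_smooth_map(traj, spikes, params, impl or "convolution")
    if params.method == "adaptive_bin":
        return adaptive_bin_map(traj, spikes, params, impl or "convolution")
    if params.method == "ksde":
        return ksde_map(traj, spikes, params, impl or "ratio_kernel")
    return _DISPATCH[params.method](traj, spikes, params)
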