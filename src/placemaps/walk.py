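"""Gaussian random-walk trajectory simulator for open-field foraging.

The agent takes one decision step per second of walk time on a coarse pixel
grid covering the arena.  Each candidate pixel is scored by the sum of five
normalized terms -- a Gaussian over step distance, a von Mises term over
heading change, inverted recent occupancy, a wall-distance term and a
center-distance term (plus an optional goal bias) -- and the argmax becomes
the next decision point.  The path between decision points is linearly
upsampled to the positional sampling rate, corrupted with uniform tracking
jitter, smoothed with a penalized spline and clamped to the arena.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solveh_banded
from scipy.special import i0

from .arena import ArenaSpec

__all__ = ["RandomWalkConfig", "Trajectory", "simulate_random_walk", "clip_trajectory"]


@dataclass(frozen=True)
class RandomWalkConfig:
    """Parameters of the decision-step random walk.

    Distances (``step_mu``, ``step_sigma``, the bias sigmas) are expressed in
    occupancy-grid pixels (default pixel = 5 mm), so the default mean step of
    64 px corresponds to 320 mm per second.
    """

    step_mu: float = 64.0
    step_sigma: float = 128.0
    vonmises_kappa: float = 1.0
    occupancy_window: float = 480.0  # seconds (8 min sliding window)
    center_sigma: float = 512.0
    wall_sigma: float = 512.0
    bias_mode: str = "uniform"  # uniform | goal | thigmotaxis
    goal_sigma: float = 25.0
    goal_downweight: float = 0.9
    thigmotaxis_wall_sigma: float = 100.0
    jitter_max: float = 85.0  # mm, uniform per coordinate
    path_smoothing: float = 128.0  # penalized-spline penalty
    upsample_factor: int = 50
    decision_concentration: float = 16.0  # sharpness of the step choice
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bias_mode not in ("uniform", "goal", "thigmotaxis"):
            raise ValueError(f"unknown bias_mode {self.bias_mode!r}")
        for name in ("step_sigma", "center_sigma", "wall_sigma", "goal_sigma",
                     "thigmotaxis_wall_sigma"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive")
        for name in ("step_mu", "occupancy_window", "jitter_max",
                     "path_smoothing", "vonmises_kappa"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled (t, x, y) path inside an arena."""

    t: np.ndarray  # s, uniform spacing 1/sample_rate
    x: np.ndarray  # mm
    y: np.ndarray  # mm
    arena: ArenaSpec = field(default_factory=ArenaSpec)

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return self.n_samples * self.arena.sample_interval

    def positions(self) -> np.ndarray:
        """(n, 2) array of xy positions."""
        return np.column_stack([self.x, self.y])


def _whittaker_smooth(y: np.ndarray, lam: float) -> np.ndarray:
    """Second-difference penalized least-squares smoother (Whittaker).

    Solves (I + lam * D2'D2) z = y with a symmetric pentadiagonal system.
    """
    n = len(y)
    if n < 3 or lam <= 0:
        return y.copy()
    # Upper banded representation of I + lam*D'D for second differences.
    ab = np.zeros((3, n))
    d0 = np.full(n, 6.0)
    d0[[0, -1]] = 1.0
    d0[[1, -2]] = 5.0
    d1 = np.full(n - 1, -4.0)
    d1[[0, -1]] = -2.0
    ab[0, 2:] = lam * 1.0
    ab[1, 1:] = lam * d1
    ab[2, :] = lam * d0 + 1.0
    return solveh_banded(ab, y)


def simulate_random_walk(
    arena: ArenaSpec,
    config: RandomWalkConfig,
    duration: float,
) -> Trajectory:
    """Simulate a seeded foraging trajectory of ``duration`` seconds.

    One decision step is taken per second; the resulting path is upsampled to
    ``arena.sample_rate`` (via ``config.upsample_factor`` samples per step),
    jittered, spline-smoothed and clamped to the arena bounds.
    """
    if not (math.isfinite(duration) and duration >= 1.0):
        raise ValueError("duration must be at least one decision step (1 s)")
    rng = np.random.default_rng(config.seed)
    res = arena.grid_resolution
    nxp = int(round(arena.width / res))
    nyp = int(round(arena.height / res))
    # Pixel-center coordinates in pixel units.
    px = (np.arange(nxp) + 0.5)
    py = (np.arange(nyp) + 0.5)
    PX, PY = np.meshgrid(px, py, indexing="ij")
    PX = PX.ravel()
    PY = PY.ravel()

    def unit(v: np.ndarray) -> np.ndarray:
        """Min-max normalize to [0, 1] (constant input -> zeros)."""
        lo, hi = v.min(), v.max()
        return (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)

    # Static terms, normalized to a unit maximum.  With the broad default
    # sigmas these are weak, shallow gradients (weak wall repulsion / center
    # attraction), as intended.
    d_wall = np.minimum.reduce([PX, nxp - PX, PY, nyp - PY])
    if config.bias_mode == "thigmotaxis":
        # attracted to walls; center attraction disabled
        wall_term = np.exp(-(d_wall**2) / (2 * config.thigmotaxis_wall_sigma**2))
        wall_term /= wall_term.max()
        center_term = np.zeros_like(wall_term)
    else:
        # weakly repelled by walls: inverted wall-proximity weight
        gw = np.exp(-(d_wall**2) / (2 * config.wall_sigma**2))
        wall_term = 1.0 - gw / gw.max()
        d_center = np.hypot(PX - nxp / 2.0, PY - nyp / 2.0)
        center_term = np.exp(-(d_center**2) / (2 * config.center_sigma**2))
        center_term /= center_term.max()

    goal_term = None
    if config.bias_mode == "goal":
        gx, gy = 0.75 * nxp, 0.5 * nyp
        d_goal = np.hypot(PX - gx, PY - gy)
        goal_term = np.exp(-(d_goal**2) / (2 * config.goal_sigma**2))
        goal_term = config.goal_downweight * goal_term / goal_term.max()

    n_steps = int(math.floor(duration))
    occ = np.zeros(nxp * nyp)
    # per-second pixel visits (the whole interpolated path corridor) within
    # the sliding occupancy window
    window_steps = max(1, int(round(config.occupancy_window)))
    visit_log: deque[np.ndarray] = deque()

    up = config.upsample_factor
    pos = np.array([nxp / 2.0, nyp / 2.0])
    heading = rng.uniform(-np.pi, np.pi)
    vm_norm = 2 * np.pi * i0(config.vonmises_kappa)
    decision = np.empty((n_steps + 1, 2))
    decision[0] = pos

    for step in range(n_steps):
        dx = PX - pos[0]
        dy = PY - pos[1]
        dist = np.hypot(dx, dy)
        step_term = unit(np.exp(-((dist - config.step_mu) ** 2)
                                / (2 * config.step_sigma**2)))
        ang = np.arctan2(dy, dx)
        vm = unit(np.exp(config.vonmises_kappa * np.cos(ang - heading)) / vm_norm)
        occ_max = occ.max()
        occ_term = 1.0 - unit(occ) if occ_max > 0 else np.ones_like(occ)
        score = step_term + vm + occ_term + wall_term + center_term
        n_terms = 5.0
        if goal_term is not None:
            score = score + goal_term
            n_terms += 1.0
        # stochastic step choice: sample a pixel with probability
        # proportional to the normalized weighted sum raised to a
        # concentration exponent (the deterministic argmax is the
        # infinite-concentration limit)
        w = (score / n_terms) ** config.decision_concentration
        nxt_idx = int(rng.choice(len(w), p=w / w.sum()))
        nxt = np.array([PX[nxt_idx], PY[nxt_idx]])
        heading = math.atan2(nxt[1] - pos[1], nxt[0] - pos[0])
        # occupancy of the full 1-s path segment, at the upsampled rate
        seg = pos[None, :] + (np.arange(1, up + 1) / up)[:, None] * (nxt - pos)[None, :]
        si = np.clip(seg[:, 0].astype(int), 0, nxp - 1)
        sj = np.clip(seg[:, 1].astype(int), 0, nyp - 1)
        visited = si * nyp + sj
        np.add.at(occ, visited, 1.0)
        visit_log.append(visited)
        if len(visit_log) > window_steps:
            np.add.at(occ, visit_log.popleft(), -1.0)
        pos = nxt
        decision[step + 1] = pos

    # Straight-line upsampling between decision points (empty arena: the
    # obstacle-avoiding route degenerates to a straight segment).
    frac = np.arange(up) / up
    seg_start = decision[:-1]
    seg_step = decision[1:] - decision[:-1]
    path = seg_start[:, None, :] + frac[None, :, None] * seg_step[:, None, :]
    path = path.reshape(-1, 2) * res  # pixels -> mm

    jitter = rng.uniform(-config.jitter_max, config.jitter_max, size=path.shape)
    path = path + jitter
    x = _whittaker_smooth(path[:, 0], config.path_smoothing)
    y = _whittaker_smooth(path[:, 1], config.path_smoothing)
    x = np.clip(x, 0.0, arena.width)
    y = np.clip(y, 0.0, arena.height)

    n = len(x)
    t = np.arange(n) * arena.sample_interval
    traj = Trajectory(t=t, x=x, y=y, arena=arena)
    want = int(round(duration * arena.sample_rate))
    if want < n:
        traj = clip_trajectory(traj, duration)
    return traj


def clip_trajectory(traj: Trajectory, duration: float) -> Trajectory:
    """Keep only the first ``duration`` seconds of a trajectory."""
    n = int(round(duration * traj.arena.sample_rate))
    if n > traj.n_samples:
        raise ValueError(
            f"cannot clip to {duration} s: trajectory is only {traj.duration} s"
        )
    return replace(traj, t=traj.t[:n].copy(), x=traj.x[:n].copy(), y=traj.y[:n].copy())
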