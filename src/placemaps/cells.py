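"""Simulated place cells: multivariate-Gaussian firing fields.

A cell's spike-probability surface is the pointwise maximum over one or more
bivariate Gaussian fields evaluated on a 1 mm grid covering the arena.  Three
size groups are supported, with mean per-axis variances of 4000, 8000 and
16000 mm^2, i.e. average field radii at two standard deviations of about
126, 179 and 253 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import ArenaSpec

__all__ = [
    "FieldParams",
    "PlaceCellModel",
    "GROUP_VARIANCE",
    "group_radius",
    "generate_field_pool",
    "simulate_place_cell",
]

#: Mean per-axis field variance (mm^2) for the three size groups.
GROUP_VARIANCE = {"small": 4000.0, "medium": 8000.0, "large": 16000.0}

#: Gamma distribution of the number of fields per cell.
FIELD_COUNT_SHAPE = 5.73
FIELD_COUNT_SCALE = 0.26

_VAR_JITTER_SD = 1000.0
_VAR_FLOOR = 1000.0
_COV_MULT_SD = 0.25

#: Peak of the per-sample spike rate surface (spikes per position sample).
#: At 50 Hz sampling this is a 100 Hz in-field peak before the spike train
#: is downsampled to the cell's target mean rate, so downsampling is the
#: binding step for typical ~1 Hz targets.
FIELD_PEAK = 2.0


def group_radius(group: str) -> float:
    """Average field radius (mm) at 2 standard deviations for a size group."""
    return 2.0 * np.sqrt(GROUP_VARIANCE[group])


@dataclass(frozen=True)
class FieldParams:
    """One Gaussian firing field: centroid (mm) and covariance (mm^2)."""

    centroid: tuple[float, float]
    var_x: float
    var_y: float
    cov_xy: float = 0.0

    def __post_init__(self) -> None:
        if self.var_x < _VAR_FLOOR or self.var_y < _VAR_FLOOR:
            raise ValueError(f"per-axis variances must be >= {_VAR_FLOOR} mm^2")
        if self.var_x * self.var_y - self.cov_xy**2 <= 0:
            raise ValueError("covariance matrix must be positive definite")

    @property
    def covariance(self) -> np.ndarray:
        return np.array([[self.var_x, self.cov_xy], [self.cov_xy, self.var_y]])

    @property
    def radius(self) -> float:
        """Field radius (mm) at 2 SD of the mean per-axis variance."""
        return 2.0 * np.sqrt(0.5 * (self.var_x + self.var_y))

    def surface(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Gaussian surface on coordinate grids, normalized to unit peak."""
        dx = X - self.centroid[0]
        dy = Y - self.centroid[1]
        det = self.var_x * self.var_y - self.cov_xy**2
        # inverse covariance quadratic form
        q = (self.var_y * dx**2 - 2 * self.cov_xy * dx * dy + self.var_x * dy**2) / det
        return np.exp(-0.5 * q)


@dataclass(frozen=True)
class PlaceCellModel:
    """Ground-truth spike-probability surface of one simulated cell.

    ``prob_map`` is sampled on a 1 mm grid (shape (nx, ny), index [i, j] at
    x = i + 0.5, y = j + 0.5 mm) and equals the pointwise maximum over the
    per-field Gaussian surfaces (unit peak each), scaled by ``FIELD_PEAK``
    spikes per position sample.
    """

    fields: tuple[FieldParams, ...]
    prob_map: np.ndarray
    mean_rate: float  # target mean firing rate, Hz
    arena: ArenaSpec

    def __post_init__(self) -> None:
        if len(self.fields) < 1:
            raise ValueError("a place cell needs at least one field")
        if np.any(self.prob_map < 0):
            raise ValueError("prob_map must be non-negative")

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    @property
    def mean_field_radius(self) -> float:
        return float(np.mean([f.radius for f in self.fields]))

    def probability_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-pixel lookup of the 1 mm probability surface."""
        nx, ny = self.prob_map.shape
        i = np.clip(np.floor(x).astype(int), 0, nx - 1)
        j = np.clip(np.floor(y).astype(int), 0, ny - 1)
        return self.prob_map[i, j]


def _prob_grid(arena: ArenaSpec) -> tuple[np.ndarray, np.ndarray]:
    nx = int(round(arena.width))
    ny = int(round(arena.height))
    gx = np.arange(nx) + 0.5
    gy = np.arange(ny) + 0.5
    return np.meshgrid(gx, gy, indexing="ij")


def generate_field_pool(
    arena: ArenaSpec,
    size_group: str,
    n_fields: int = 512,
    seed: int | np.random.Generator = 0,
) -> list[FieldParams]:
    """Draw a pool of firing fields for one size group.

    Per-axis variances are drawn independently as N(group mean, 1000^2)
    clipped at 1000 mm^2; the xy covariance is the mean per-axis variance
    times a N(0, 0.25^2) multiplier clipped to [-1, 1] (redrawn if it would
    make the covariance matrix singular); centroids are uniform in the arena.
    """
    if size_group not in GROUP_VARIANCE:
        raise ValueError(f"unknown size group {size_group!r}")
    if n_fields < 1:
        raise ValueError("empty field pool")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mean_var = GROUP_VARIANCE[size_group]
    pool = []
    for _ in range(n_fields):
        var_x = max(_VAR_FLOOR, rng.normal(mean_var, _VAR_JITTER_SD))
        var_y = max(_VAR_FLOOR, rng.normal(mean_var, _VAR_JITTER_SD))
        vbar = 0.5 * (var_x + var_y)
        while True:
            mult = np.clip(rng.normal(0.0, _COV_MULT_SD), -1.0, 1.0)
            cov = vbar * mult
            if var_x * var_y - cov**2 > 0:
                break
        cx = rng.uniform(0.0, arena.width)
        cy = rng.uniform(0.0, arena.height)
        pool.append(FieldParams((cx, cy), var_x, var_y, cov))
    return pool


def simulate_place_cell(
    arena: ArenaSpec,
    size_group: str,
    field_pool: list[FieldParams] | None = None,
    seed: int | np.random.Generator = 0,
) -> PlaceCellModel:
    """Simulate one place cell of the given size group.

    The number of fields is a gamma(5.73, 0.26) draw clipped above 1 and
    rounded; fields are sampled without replacement from the pool; the target
    mean rate is N(1, 1) Hz clipped to [0.5, 10].
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if field_pool is None:
        field_pool = generate_field_pool(arena, size_group, seed=rng)
    if len(field_pool) == 0:
        raise ValueError("empty field pool")
    n = int(round(max(1.0, rng.gamma(FIELD_COUNT_SHAPE, FIELD_COUNT_SCALE))))
    n = max(1, min(n, len(field_pool)))
    idx = rng.choice(len(field_pool), size=n, replace=False)
    fields = tuple(field_pool[i] for i in idx)
    X, Y = _prob_grid(arena)
    prob = np.zeros_like(X)
    for f in fields:
        np.maximum(prob, f.surface(X, Y), out=prob)
    prob *= FIELD_PEAK
    rate = float(np.clip(rng.normal(1.0, 1.0), 0.5, 10.0))
    return PlaceCellModel(fields=fields, prob_map=prob, mean_rate=rate, arena=arena)
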