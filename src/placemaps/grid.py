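"""Spatial binning: map grids, dwell maps and spike maps.

Bins are left-closed right-open squares; a grid of ``nx = ceil(width / h)``
bins is centered symmetrically on the arena.  Points lying exactly on the
maximum edge of the grid are assigned to the last bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .arena import ArenaSpec
from .spiking import SpikeTrain
from .walk import Trajectory

__all__ = ["MapGrid", "DwellMap", "SpikeMap", "bin_data"]


@dataclass(frozen=True)
class MapGrid:
    """A regular grid of square bins of side ``h`` mm."""

    x0: float
    y0: float
    h: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("bin side h must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one bin per axis")

    @classmethod
    def for_arena(cls, arena: ArenaSpec, h: float) -> "MapGrid":
        """Grid of ceil(extent / h) bins per axis, centered on the arena."""
        nx = math.ceil(arena.width / h)
        ny = math.ceil(arena.height / h)
        x0 = arena.width / 2.0 - nx * h / 2.0
        y0 = arena.height / 2.0 - ny * h / 2.0
        return cls(x0=x0, y0=y0, h=h, nx=nx, ny=ny)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def bin_area(self) -> float:
        """Bin area in mm^2."""
        return self.h * self.h

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = self.x0 + (np.arange(self.nx) + 0.5) * self.h
        cy = self.y0 + (np.arange(self.ny) + 0.5) * self.h
        return cx, cy

    def center_points(self) -> np.ndarray:
        """(nx*ny, 2) bin-center coordinates, row-major over (i, j)."""
        cx, cy = self.bin_centers()
        X, Y = np.meshgrid(cx, cy, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])

    def bin_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Left-closed right-open bin indices; max-edge points go to the last bin."""
        i = np.floor((np.asarray(x) - self.x0) / self.h).astype(int)
        j = np.floor((np.asarray(y) - self.y0) / self.h).astype(int)
        # points exactly on the upper grid edge belong to the last bin
        i = np.where((i == self.nx) & np.isclose(x, self.x0 + self.nx * self.h), self.nx - 1, i)
        j = np.where((j == self.ny) & np.isclose(y, self.y0 + self.ny * self.h), self.ny - 1, j)
        if np.any((i < 0) | (i >= self.nx) | (j < 0) | (j >= self.ny)):
            raise ValueError("points outside the grid extent")
        return i, j


@dataclass(frozen=True)
class DwellMap:
    """Per-bin dwell time in seconds (position counts x sampling interval)."""

    grid: MapGrid
    values: np.ndarray  # seconds, shape grid.shape

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class SpikeMap:
    """Per-bin spike counts."""

    grid: MapGrid
    values: np.ndarray  # counts, shape grid.shape

    @property
    def total(self) -> float:
        return float(self.values.sum())


def _count(grid: MapGrid, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    counts = np.zeros(grid.shape)
    if len(x):
        i, j = grid.bin_index(x, y)
        np.add.at(counts, (i, j), 1.0)
    return counts


def bin_data(
    traj: Trajectory, spikes: SpikeTrain, grid: MapGrid
) -> tuple[DwellMap, SpikeMap]:
    """Exact crosstabulation of position samples and spikes into ``grid``.

    The dwell map sums to ``n_samples * f_s`` and the spike map to
    ``n_spikes`` exactly.
    """
    if traj.n_samples == 0:
        raise ValueError("empty trajectory")
    fs = traj.arena.sample_interval
    dwell = _count(grid, traj.x, traj.y) * fs
    spike = _count(grid, spikes.spike_x, spikes.spike_y)
    return DwellMap(grid, dwell), SpikeMap(grid, spike)
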