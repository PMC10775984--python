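"""Scoring rate maps against the ground-truth spike-probability surface.

The headline metric is the mean integrated squared error (MISE) between the
estimated map and the cell's true probability surface, both normalized to
unit sum over the jointly defined 1 mm support; units are integrated
probability squared, not firing rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .cells import PlaceCellModel
from .mapping import RateMap

__all__ = [
    "ErrorReport",
    "upsample_to_mm",
    "mise",
    "detect_fields",
    "field_detect_error",
    "empty_proportion",
    "alt_metrics",
    "evaluate_map",
]

#: minimum contiguous area (mm^2) for a detected place field: 36 cm^2
FIELD_AREA_MIN = 3600.0
FIELD_THRESHOLD = 0.2


@dataclass(frozen=True)
class ErrorReport:
    """Per-map objective values used by the parameter optimization."""

    mise: float
    field_detect_error: int
    empty_proportion: float
    compute_time: float = float("nan")  # s, wall clock around map construction
    pearson_r: float = float("nan")
    euclidean: float = float("nan")


def upsample_to_mm(ratemap: RateMap, arena) -> np.ndarray:
    """Nearest-neighbour upsampling of a rate map to the 1 mm arena grid.

    Cells of the 1 mm grid whose parent bin is missing, or which fall
    outside the map grid, are NaN.
    """
    nx = int(round(arena.width))
    ny = int(round(arena.height))
    gx = np.arange(nx) + 0.5
    gy = np.arange(ny) + 0.5
    g = ratemap.grid
    i = np.floor((gx - g.x0) / g.h).astype(int)
    j = np.floor((gy - g.y0) / g.h).astype(int)
    ok_i = (i >= 0) & (i < g.nx)
    ok_j = (j >= 0) & (j < g.ny)
    out = np.full((nx, ny), np.nan)
    ii = np.clip(i, 0, g.nx - 1)
    jj = np.clip(j, 0, g.ny - 1)
    out[np.ix_(ok_i, ok_j)] = ratemap.rate[np.ix_(ii[ok_i], jj[ok_j])]
    return out


def mise(ratemap: RateMap, truth: PlaceCellModel) -> float:
    """Mean integrated squared error between map and truth.

    Both surfaces are normalized to unit sum over the jointly non-missing
    1 mm support; the integral is the Riemann sum over 1 mm cells with
    dx = dy = 1.
    """
    est = upsample_to_mm(ratemap, truth.arena)
    valid = ~np.isnan(est)
    if not valid.any():
        raise ValueError("rate map is fully missing")
    r = est[valid]
    f = truth.prob_map[valid]
    rs = r.sum()
    fs_ = f.sum()
    r = r / rs if rs > 0 else r
    f = f / fs_ if fs_ > 0 else f
    return float(((r - f) ** 2).sum())


def detect_fields(
    surface: np.ndarray,
    bin_area: float = 1.0,
    connectivity: int = 2,
) -> int:
    """Count place fields in a rate or probability surface.

    The surface is thresholded at 20% of its maximum (missing bins count as
    below threshold) and contiguous regions larger than 36 cm^2 are counted.
    ``bin_area`` is the area of one surface element in mm^2;
    ``connectivity=2`` is 8-connectivity.
    """
    finite = surface[~np.isnan(surface)]
    if finite.size == 0:
        raise ValueError("surface has no finite values")
    peak = finite.max()
    if peak <= 0:
        return 0
    above = np.where(np.isnan(surface), False, surface >= FIELD_THRESHOLD * peak)
    labels = measure.label(above, connectivity=connectivity)
    counts = np.bincount(labels.ravel())
    # label 0 is background
    return int(np.sum(counts[1:] * bin_area > FIELD_AREA_MIN))


def field_detect_error(ratemap: RateMap, truth: PlaceCellModel) -> int:
    """|fields detected in the map - fields in the 1 mm truth surface|."""
    n_map = detect_fields(ratemap.rate, bin_area=ratemap.grid.bin_area)
    n_truth = detect_fields(truth.prob_map, bin_area=1.0)
    return abs(n_map - n_truth)


def empty_proportion(ratemap: RateMap) -> float:
    """Fraction of bins that are missing (NaN; zero-rate bins do not count)."""
    return float(np.isnan(ratemap.rate).mean())


def alt_metrics(ratemap: RateMap, truth: PlaceCellModel) -> tuple[float, float]:
    """(Pearson r, Euclidean distance) on the same support as MISE."""
    est = upsample_to_mm(ratemap, truth.arena)
    valid = ~np.isnan(est)
    r = est[valid]
    f = truth.prob_map[valid]
    rs, fs_ = r.sum(), f.sum()
    r = r / rs if rs > 0 else r
    f = f / fs_ if fs_ > 0 else f
    if np.std(r) == 0 or np.std(f) == 0:
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(r, f)[0, 1])
    return pearson, float(np.sqrt(((r - f) ** 2).sum()))


def evaluate_map(
    ratemap: RateMap,
    truth: PlaceCellModel,
    compute_time: float = float("nan"),
    with_alt: bool = False,
) -> ErrorReport:
    """Full error report for one map against one cell."""
    pearson, euclid = alt_metrics(ratemap, truth) if with_alt else (float("nan"),) * 2
    return ErrorReport(
        mise=mise(ratemap, truth),
        field_detect_error=field_detect_error(ratemap, truth),
        empty_proportion=empty_proportion(ratemap),
        compute_time=compute_time,
        pearson_r=pearson,
        euclidean=euclid,
    )
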