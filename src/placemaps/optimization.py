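"""Parameter sweeps, Pareto-optimal selection and parameter regressions.

A sweep evaluates every (bin size, smoothing) pair of a grid for one method
over a set of simulated cells, averaging four objectives per pair: MISE,
computation time, proportion of empty bins and place-field detection error.
The non-dominated subset of the grid is the Pareto front; the "balanced"
solution is the front member closest (in min-max normalized MISE x time
space) to the utopia point.  Linear regressions of the selected bin size
and smoothing on field radius r (mm) and duration d (min) summarize how the
optimum moves with the data, and published default coefficients are shipped
for plug-in use.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import ErrorReport, evaluate_map
from .mapping import MapParams, make_map

__all__ = [
    "SweepResult",
    "ParetoSolution",
    "RegressionFit",
    "sweep",
    "pareto_front",
    "select_balanced",
    "fit_parameter_regression",
    "predict_parameters",
    "TABLE1_DEFAULTS",
    "SMALLEST_AVAILABLE",
]

SMALLEST_AVAILABLE = "smallest_available"

#: Published plug-in coefficients (b0, b_r, b_d) for bin size and smoothing
#: as linear functions of field radius r (mm) and duration d (min), per
#: method and solution type.  ``SMALLEST_AVAILABLE`` marks bin-size entries
#: that should simply use the smallest bin size the data permit.
TABLE1_DEFAULTS: dict[str, dict[str, dict[str, tuple | str]]] = {
    "histogram": {
        "min_error": {"bin_size": SMALLEST_AVAILABLE,
                      "smoothing": (16.232, 0.119, -0.218)},
        "balanced": {"bin_size": (22.229, 0.115, -0.413),
                     "smoothing": (9.900, 0.278, -0.617)},
    },
    "ash": {
        "min_error": {"bin_size": (76.339, 0.055, -0.278),
                      "smoothing": (-29.982, 0.328, -0.085)},
        "balanced": {"bin_size": (56.510, 0.259, -0.513),
                     "smoothing": (5.338, -0.006, -0.006)},
    },
    "adaptive_smooth": {
        "min_error": {"bin_size": (1.7615, 0.0077, -0.0050),
                      "smoothing": (-11872.0, 125.0, 281.0)},
        "balanced": {"bin_size": (9.714, 0.041, 0.104),
                     "smoothing": (-9917.0, 61.0, 106.0)},
    },
    "adaptive_bin": {
        "min_error": {"bin_size": (1.606, -0.004, 0.009),
                      "smoothing": (-5.078, 0.041, 0.050)},
        "balanced": {"bin_size": (-5.451, 0.135, -0.055),
                     "smoothing": (-4.336, 0.036, 0.045)},
    },
    "ksde": {
        "min_error": {"bin_size": SMALLEST_AVAILABLE,
                      "smoothing": (17.685, 0.133, -0.768)},
        "balanced": {"bin_size": (9.900, 0.099, -0.325),
                     "smoothing": (14.806, 0.139, -0.707)},
    },
    "tksde": {
        "min_error": {"bin_size": (3.529, 0.014, -0.020),
                      "smoothing": (10.949, 0.213, -0.179)},
        "balanced": {"bin_size": (14.720, 0.104, -0.188),
                     "smoothing": (19.304, 0.242, -0.222)},
    },
}

OBJECTIVES = ("mise", "compute_time", "empty_proportion", "field_detect_error")


@dataclass(frozen=True)
class SweepResult:
    """Mean objectives over cells for every grid combination of one method."""

    method: str
    bin_sizes: np.ndarray
    smoothings: np.ndarray
    mise: np.ndarray  # (n_bins, n_smooth)
    compute_time: np.ndarray
    empty_proportion: np.ndarray
    field_detect_error: np.ndarray
    n_cells: int = 0
    duration: float = float("nan")
    size_group: str = ""

    def objective_matrix(self) -> np.ndarray:
        """(n_combinations, 4) matrix in OBJECTIVES order, row-major grid."""
        return np.column_stack([getattr(self, k).ravel() for k in OBJECTIVES])

    def combinations(self) -> np.ndarray:
        """(n_combinations, 2) array of (bin size, smoothing) pairs."""
        B, S = np.meshgrid(self.bin_sizes, self.smoothings, indexing="ij")
        return np.column_stack([B.ravel(), S.ravel()])

    def to_dataframe(self) -> pd.DataFrame:
        combos = self.combinations()
        df = pd.DataFrame(combos, columns=["bin_size", "smoothing"])
        for k in OBJECTIVES:
            df[k] = getattr(self, k).ravel()
        df.insert(0, "method", self.method)
        return df

    def min_error_combination(self) -> tuple[float, float]:
        idx = np.nanargmin(self.mise)
        i, j = np.unravel_index(idx, self.mise.shape)
        return float(self.bin_sizes[i]), float(self.smoothings[j])


@dataclass(frozen=True)
class ParetoSolution:
    """The Pareto front of a sweep plus the selected compromise points."""

    front_indices: np.ndarray  # indices into the sweep's row-major grid
    front_params: np.ndarray  # (k, 2) bin size, smoothing
    front_objectives: np.ndarray  # (k, 4)
    balanced: tuple[float, float]
    min_error: tuple[float, float]


def sweep(
    method: str,
    cells,
    trajectories,
    bin_sizes,
    smoothings,
    impl: str | None = None,
    timing_repeats: int = 1,
    map_kwargs: dict | None = None,
) -> SweepResult:
    """Evaluate a full (bin size x smoothing) grid for ``method``.

    ``cells`` is a sequence of PlaceCellModel with paired spike trains:
    each element is a (cell, spikes) tuple; ``trajectories`` is either one
    Trajectory shared by all cells or a sequence assigned cyclically.
    A failed map build leaves that cell out of the combination's mean rather
    than aborting the sweep.
    """
    bin_sizes = np.asarray(bin_sizes, dtype=float)
    smoothings = np.asarray(smoothings, dtype=float)
    try:
        n_traj = len(trajectories)
    except TypeError:
        trajectories = [trajectories]
        n_traj = 1
    shape = (len(bin_sizes), len(smoothings))
    sums = {k: np.zeros(shape) for k in OBJECTIVES}
    counts = np.zeros(shape)
    for ci, (cell, spikes) in enumerate(cells):
        traj = trajectories[ci % n_traj]
        for bi, b in enumerate(bin_sizes):
            for si, s in enumerate(smoothings):
                params = MapParams(method=method, bin_size=float(b),
                                   smoothing=float(s), **(map_kwargs or {}))
                try:
                    times = []
                    for _ in range(max(1, timing_repeats)):
                        t0 = time.perf_counter()
                        rmap = make_map(traj, spikes, params, impl=impl)
                        times.append(time.perf_counter() - t0)
                    report = evaluate_map(rmap, cell,
                                          compute_time=float(np.median(times)))
                except (ValueError, FloatingPointError):
                    continue
                for k in OBJECTIVES:
                    sums[k][bi, si] += getattr(report, k)
                counts[bi, si] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        means = {k: sums[k] / counts for k in OBJECTIVES}
    duration = trajectories[0].duration
    return SweepResult(method=method, bin_sizes=bin_sizes, smoothings=smoothings,
                       n_cells=len(cells), duration=duration, **means)


def pareto_front(objectives: np.ndarray | SweepResult) -> np.ndarray:
    """Indices of the non-dominated rows of an objectives matrix.

    A row is dominated if some other row is <= on every objective and < on
    at least one.  All objectives are minimized.  Rows containing NaN are
    never part of the front.
    """
    if isinstance(objectives, SweepResult):
        objectives = objectives.objective_matrix()
    obj = np.asarray(objectives, dtype=float)
    n = len(obj)
    valid = ~np.isnan(obj).any(axis=1)
    keep = np.zeros(n, dtype=bool)
    for i in range(n):
        if not valid[i]:
            continue
        le = np.all(obj[valid] <= obj[i], axis=1)
        lt = np.any(obj[valid] < obj[i], axis=1)
        keep[i] = not np.any(le & lt)
    return np.flatnonzero(keep)


def select_balanced(
    front_objectives: np.ndarray,
    mise_col: int = 0,
    time_col: int = 1,
) -> int:
    """Index of the front member closest to the utopia point.

    MISE and computation time are min-max normalized over the front; the
    utopia point is (0, 0) in that space (the per-objective front minima).
    Ties break toward the smaller MISE.
    """
    obj = np.asarray(front_objectives, dtype=float)
    if len(obj) == 0:
        raise ValueError("empty Pareto front")
    m = obj[:, mise_col]
    t = obj[:, time_col]

    def norm(v: np.ndarray) -> np.ndarray:
        rng = v.max() - v.min()
        return (v - v.min()) / rng if rng > 0 else np.zeros_like(v)

    d = np.hypot(norm(m), norm(t))
    best = np.flatnonzero(d == d.min())
    if len(best) > 1:
        best = best[np.argsort(m[best], kind="stable")]
    return int(best[0])


def optimize_sweep(result: SweepResult) -> ParetoSolution:
    """Pareto front + balanced and minimum-error selections for a sweep."""
    obj = result.objective_matrix()
    combos = result.combinations()
    idx = pareto_front(obj)
    bal = idx[select_balanced(obj[idx])]
    return ParetoSolution(
        front_indices=idx,
        front_params=combos[idx],
        front_objectives=obj[idx],
        balanced=(float(combos[bal, 0]), float(combos[bal, 1])),
        min_error=result.min_error_combination(),
    )


@dataclass(frozen=True)
class RegressionFit:
    """OLS planes bin = b0 + b_r r + b_d d (and likewise for smoothing)."""

    bin_coef: tuple[float, float, float]
    smooth_coef: tuple[float, float, float]
    method: str = ""
    solution_type: str = ""
    design: pd.DataFrame | None = field(default=None, repr=False)

    def predict(self, r: float, d: float) -> tuple[float, float]:
        b0, br, bd = self.bin_coef
        s0, sr, sd = self.smooth_coef
        return b0 + br * r + bd * d, s0 + sr * r + sd * d

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps({
            "method": self.method, "solution_type": self.solution_type,
            "bin_coef": list(self.bin_coef),
            "smooth_coef": list(self.smooth_coef)}, indent=1))

    @classmethod
    def from_json(cls, path) -> "RegressionFit":
        import json
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        return cls(tuple(d["bin_coef"]), tuple(d["smooth_coef"]),
                   d.get("method", ""), d.get("solution_type", ""))


def fit_parameter_regression(
    r: np.ndarray,
    d: np.ndarray,
    bin_size: np.ndarray,
    smoothing: np.ndarray,
    method: str = "",
    solution_type: str = "",
) -> RegressionFit:
    """Least-squares planes for bin size and smoothing over an (r, d) design.

    ``r`` is field radius in mm, ``d`` duration in minutes.  At least six
    design points with full column rank are required.
    """
    r = np.asarray(r, dtype=float)
    d = np.asarray(d, dtype=float)
    if len(r) < 6:
        raise ValueError("need at least 6 design points")
    X = np.column_stack([np.ones_like(r), r, d])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design (r, d must vary independently)")
    cb, *_ = np.linalg.lstsq(X, np.asarray(bin_size, dtype=float), rcond=None)
    cs, *_ = np.linalg.lstsq(X, np.asarray(smoothing, dtype=float), rcond=None)
    design = pd.DataFrame({"r": r, "d": d, "bin_size": bin_size, "smoothing": smoothing})
    return RegressionFit(tuple(cb), tuple(cs), method, solution_type, design)


def predict_parameters(
    method: str,
    solution_type: str,
    r: float,
    d: float,
    fit: RegressionFit | None = None,
    min_bin_size: float = 1.0,
) -> tuple[float, float]:
    """(bin size mm, smoothing) for a field radius r (mm) and duration d (min).

    With no ``fit``, the published default coefficients are used;
    "smallest available" bin-size entries return ``min_bin_size``.
    """
    if r <= 0 or d <= 0:
        raise ValueError("field radius and duration must be positive")
    if fit is not None:
        return fit.predict(r, d)
    entry = TABLE1_DEFAULTS[method][solution_type]
    bc = entry["bin_size"]
    b = min_bin_size if bc == SMALLEST_AVAILABLE else bc[0] + bc[1] * r + bc[2] * d
    s0, sr, sd = entry["smoothing"]
    return float(b), float(s0 + sr * r + sd * d)
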