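"""Model / results interface over the six rate-map estimators.

``RateMapEstimator`` is constructed from data (a trajectory and a spike
train, or plain DataFrames) plus a method and its parameters; ``fit()``
performs the estimation and returns a ``RateMapResult`` carrying the map,
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .arena import ArenaSpec
from .cells import PlaceCellModel
from .evaluation import ErrorReport, empty_proportion, evaluate_map
from .mapping import METHODS, MapParams, RateMap, make_map
from .spiking import SpikeTrain
from .walk import Trajectory

__all__ = ["RateMapEstimator", "RateMapResult"]


class RateMapEstimator:
    """Firing-rate map model for one cell in one session.

    Parameters
    ----------
    trajectory : Trajectory
        Position samples at a fixed rate.
    spikes : SpikeTrain
        The cell's spike times and positions.
    method : str
        One of ``histogram``, ``ash``, ``adaptive_smooth``, ``adaptive_bin``,
        ``ksde``, ``tksde``.
    bin_size : float
        Bin side / query spacing in mm.
    smoothing : float
        Method-specific smoothing value (sigma mm, m, alpha, t s,
        bandwidth mm, or spatial sigma mm).
    impl : str, optional
        ``pixelwise`` / ``convolution`` for the adaptive methods,
        ``ratio_kernel`` / ``native`` for the KSDE.
    """

    def __init__(
        self,
        trajectory: Trajectory,
        spikes: SpikeTrain,
        method: str = "histogram",
        bin_size: float = 40.0,
        smoothing: float = 0.0,
        impl: str | None = None,
        **options: Any,
    ) -> None:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
        self.trajectory = trajectory
        self.spikes = spikes
        self.params = MapParams(method=method, bin_size=bin_size,
                                smoothing=smoothing, **options)
        self.impl = impl

    @classmethod
    def from_dataframe(
        cls,
        positions: pd.DataFrame,
        spikes: pd.DataFrame,
        arena: ArenaSpec | None = None,
        **kwargs: Any,
    ) -> "RateMapEstimator":
        """Build from DataFrames with columns (t, x, y) / (spike_t, spike_x, spike_y)."""
        arena = arena or ArenaSpec()
        traj = Trajectory(t=positions["t"].to_numpy(float),
                          x=positions["x"].to_numpy(float),
                          y=positions["y"].to_numpy(float), arena=arena)
        st = SpikeTrain(spike_t=spikes["spike_t"].to_numpy(float),
                        spike_x=spikes["spike_x"].to_numpy(float),
                        spike_y=spikes["spike_y"].to_numpy(float))
        return cls(traj, st, **kwargs)

    def fit(self) -> "RateMapResult":
        """Estimate the rate map; wall-clock time is recorded."""
        t0 = time.perf_counter()
        rmap = make_map(self.trajectory, self.spikes, self.params, impl=self.impl)
        elapsed = time.perf_counter() - t0
        return RateMapResult(model=self, ratemap=rmap, compute_time=elapsed)


@dataclass
class RateMapResult:
    """A fitted firing-rate map with diagnostics."""

    model: RateMapEstimator
    ratemap: RateMap
    compute_time: float
    _score: ErrorReport | None = field(default=None, repr=False)

    @property
    def rate(self) -> np.ndarray:
        return self.ratemap.rate

    @property
    def grid(self):
        return self.ratemap.grid

    def score(self, truth: PlaceCellModel, with_alt: bool = False) -> ErrorReport:
        """Error report against a ground-truth probability surface."""
        self._score = evaluate_map(self.ratemap, truth,
                                   compute_time=self.compute_time,
                                   with_alt=with_alt)
        return self._score

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        r = self.ratemap
        finite = r.rate[~np.isnan(r.rate)]
        dur = self.model.trajectory.duration
        rows = [
            ("Method", r.method),
            ("Bin size (mm)", f"{r.grid.h:g}"),
            ("Smoothing", f"{self.model.params.smoothing:g}"),
            ("Grid", f"{r.grid.nx} x {r.grid.ny}"),
            ("Session duration (s)", f"{dur:.1f}"),
            ("Spikes", f"{self.model.spikes.n_spikes}"),
            ("Mean rate (data, Hz)", f"{self.model.spikes.n_spikes / dur:.3f}"),
            ("Peak rate (map, Hz)", f"{finite.max():.3f}" if finite.size else "n/a"),
            ("Mean rate (map, Hz)", f"{np.nanmean(r.rate):.3f}" if finite.size else "n/a"),
            ("Empty proportion", f"{empty_proportion(r):.3f}"),
            ("Compute time (s)", f"{self.compute_time:.4f}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Firing Rate Map Results", "=" * 38]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        if self._score is not None:
            lines += ["-" * 38,
                      f"{'MISE':<{width}}  {self._score.mise:.3e}",
                      f"{'Field detect error':<{width}}  {self._score.field_detect_error}"]
        return "\n".join(lines)

    def plot(self, ax=None, cmap: str = "viridis"):
        """Draw the map (NaN bins transparent); returns the Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.ratemap.grid
        extent = (g.x0, g.x0 + g.nx * g.h, g.y0, g.y0 + g.ny * g.h)
        im = ax.imshow(self.ratemap.rate.T, origin="lower", extent=extent,
                       cmap=cmap, interpolation="nearest")
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        ax.set_title(f"{self.ratemap.method} rate map")
        plt.colorbar(im, ax=ax, label="Hz")
        return ax

    def save(self, path):
        from .io import save_ratemap

        return save_ratemap(self.ratemap, path)
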