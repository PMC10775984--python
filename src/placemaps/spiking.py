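"""Poisson spike generation along a trajectory.

Per position sample the spike count is Poisson with rate equal to the cell's
spike probability at the (time-jittered) position, plus a small Poisson
background.  The raw train is then uniformly downsampled to the cell's
target mean firing rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cells import PlaceCellModel
from .walk import Trajectory

__all__ = ["SpikeTrain", "simulate_spikes"]


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (s) with the trajectory positions at which they occurred."""

    spike_t: np.ndarray
    spike_x: np.ndarray
    spike_y: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.spike_t) == len(self.spike_x) == len(self.spike_y)):
            raise ValueError("spike arrays must have equal length")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_t)

    def positions(self) -> np.ndarray:
        return np.column_stack([self.spike_x, self.spike_y])


def simulate_spikes(
    cell: PlaceCellModel,
    traj: Trajectory,
    background_lambda: float = 0.001,
    jitter_mu: float = 0.01,
    jitter_sigma: float = 0.02,
    overdispersion: bool = False,
    seed: int | np.random.Generator = 0,
) -> SpikeTrain:
    """Generate a spike train for ``cell`` along ``traj``.

    The spike-probability vector sampled along the trajectory is randomly
    time-shifted per sample (shift magnitude ~ N(jitter_mu, jitter_sigma)
    seconds, random sign) before the Poisson draw; with ``overdispersion`` it
    is additionally multiplied by a 1.5 Hz oscillation ranging 0.2-1.8.
    Spikes are finally downsampled without replacement to the cell's target
    mean rate; if too few raw spikes exist a warning is issued and all raw
    spikes are returned.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fs = traj.arena.sample_interval
    n = traj.n_samples
    lam = cell.probability_at(traj.x, traj.y)

    # time-shift the probability values along the trajectory
    shift_s = rng.normal(jitter_mu, jitter_sigma, size=n)
    sign = rng.choice([-1, 1], size=n)
    shift = np.rint(sign * shift_s / fs).astype(int)
    idx = np.clip(np.arange(n) + shift, 0, n - 1)
    lam = lam[idx]

    if overdispersion:
        # 1.5 Hz multiplicative modulation, mean 1.0, range [0.2, 1.8]
        lam = lam * (1.0 + 0.8 * np.sin(2 * np.pi * 1.5 * traj.t))

    counts = rng.poisson(lam) + rng.poisson(background_lambda, size=n)
    spike_sample = np.repeat(np.arange(n), counts)

    target = int(np.floor(cell.mean_rate * traj.duration))
    if len(spike_sample) < target:
        warnings.warn(
            f"only {len(spike_sample)} raw spikes for a target of {target}; "
            "returning all raw spikes",
            stacklevel=2,
        )
    elif target < len(spike_sample):
        keep = rng.choice(len(spike_sample), size=target, replace=False)
        spike_sample = np.sort(spike_sample[keep])

    return SpikeTrain(
        spike_t=traj.t[spike_sample].copy(),
        spike_x=traj.x[spike_sample].copy(),
        spike_y=traj.y[spike_sample].copy(),
    )
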