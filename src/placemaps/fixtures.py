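"""Deterministic fixture generation: bundled simulated sessions on disk."""

from __future__ import annotations

import json
from pathlib import Path

from .arena import ArenaSpec
from .cells import generate_field_pool, simulate_place_cell
from .io import SessionBundle, save_cell, write_spikes, write_trajectory
from .spiking import simulate_spikes
from .walk import RandomWalkConfig, simulate_random_walk

__all__ = ["make_fixtures", "PROFILES"]

#: profile -> (n_cells, durations in minutes, size groups used)
PROFILES = {
    "smoke": (2, (4,), ("medium",)),
    "bench_small": (24, (4, 16), ("small", "medium", "large")),
}


def make_fixtures(profile: str, seed: int, out_dir) -> list[SessionBundle]:
    """Write a deterministic tree of simulated sessions with ground truth.

    ``smoke`` is 2 cells x 4 min; ``bench_small`` is 24 cells x {4, 16} min
    spread over the three field-size groups.  The same seed always yields
    byte-identical files.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    n_cells, durations, groups = PROFILES[profile]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arena = ArenaSpec()
    max_minutes = max(durations)
    n_traj = min(8, n_cells)
    trajs = [
        simulate_random_walk(arena,
                             RandomWalkConfig(seed=seed * 1009 + k),
                             duration=max_minutes * 60.0)
        for k in range(n_traj)
    ]
    pools = {g: generate_field_pool(arena, g, seed=seed * 7919 + gi)
             for gi, g in enumerate(groups)}
    bundles = []
    for ci in range(n_cells):
        group = groups[ci % len(groups)]
        cell = simulate_place_cell(arena, group, pools[group],
                                   seed=seed * 104729 + ci)
        traj_full = trajs[ci % n_traj]
        for minutes in durations:
            from .walk import clip_trajectory

            traj = clip_trajectory(traj_full, minutes * 60.0)
            spikes = simulate_spikes(cell, traj, seed=seed * 1299709 + ci)
            stem = out / f"cell{ci:03d}_{group}_{minutes}min"
            tp = write_trajectory(traj, stem.with_name(stem.name + "_pos.csv"))
            sp = write_spikes(spikes, stem.with_name(stem.name + "_spk.csv"))
            cp = save_cell(cell, stem.with_name(stem.name + "_cell"))
            meta = {
                "seed": seed, "cell": ci, "group": group,
                "duration_min": minutes, "n_spikes": spikes.n_spikes,
                "mean_rate_target": cell.mean_rate,
            }
            mp = stem.with_name(stem.name + "_meta.json")
            mp.write_text(json.dumps(meta, indent=1))
            bundles.append(SessionBundle(tp, sp, cp, meta))
    return bundles
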