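"""File formats: CSV sessions, portable rate-map and cell containers.

Interchange is plain CSV (units mm and s declared in a leading comment
line) with JSON sidecars for metadata; rasters (rate maps, probability
surfaces) are stored as ``.npz`` with grid geometry in the sidecar.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import ArenaSpec
from .cells import FieldParams, PlaceCellModel
from .grid import MapGrid
from .mapping import RateMap
from .spiking import SpikeTrain
from .walk import Trajectory

__all__ = [
    "SessionBundle",
    "write_trajectory", "read_trajectory",
    "write_spikes", "read_spikes",
    "read_session",
    "save_ratemap", "load_ratemap",
    "save_cell", "load_cell",
]


@dataclass(frozen=True)
class SessionBundle:
    """Paths making up one simulated recording session."""

    trajectory_path: Path
    spikes_path: Path
    cell_path: Path | None = None
    metadata: dict | None = None


def _read_csv(path) -> pd.DataFrame:
    # round_trip parsing so write -> read is bit-exact
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_trajectory(traj: Trajectory, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y})
    with open(path, "w") as fh:
        fh.write("# trajectory: t in s, x/y in mm\n")
        df.to_csv(fh, index=False, float_format="%.17g")  # exact round-trip
    return path


def read_trajectory(path, arena: ArenaSpec | None = None) -> Trajectory:
    df = _read_csv(path)
    for col in ("t", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df[["t", "x", "y"]].isna().any().any():
        raise ValueError(f"{path}: NaN values in trajectory")
    df = df.sort_values("t", kind="stable").reset_index(drop=True)
    t = df["t"].to_numpy(float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: duplicate or non-monotone timestamps")
    arena = arena or ArenaSpec()
    return Trajectory(t=t, x=df["x"].to_numpy(float), y=df["y"].to_numpy(float),
                      arena=arena)


def write_spikes(spikes: SpikeTrain, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"spike_t": spikes.spike_t,
                       "spike_x": spikes.spike_x,
                       "spike_y": spikes.spike_y})
    with open(path, "w") as fh:
        fh.write("# spikes: spike_t in s, spike_x/spike_y in mm\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_spikes(path) -> SpikeTrain:
    df = _read_csv(path)
    for col in ("spike_t", "spike_x", "spike_y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df.isna().any().any():
        raise ValueError(f"{path}: NaN values in spike data")
    df = df.sort_values("spike_t", kind="stable").reset_index(drop=True)
    return SpikeTrain(spike_t=df["spike_t"].to_numpy(float),
                      spike_x=df["spike_x"].to_numpy(float),
                      spike_y=df["spike_y"].to_numpy(float))


def read_session(
    trajectory_path, spikes_path, arena: ArenaSpec | None = None
) -> tuple[Trajectory, SpikeTrain]:
    """Read and validate a (trajectory, spikes) pair of CSV files."""
    return read_trajectory(trajectory_path, arena), read_spikes(spikes_path)


def save_ratemap(rmap: RateMap, path) -> Path:
    """Rate map raster as .npz with a JSON sidecar for grid geometry."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), rate=rmap.rate)
    sidecar = {
        "units": "Hz",
        "method": rmap.method,
        "params": rmap.params,
        "grid": {"x0": rmap.grid.x0, "y0": rmap.grid.y0, "h": rmap.grid.h,
                 "nx": rmap.grid.nx, "ny": rmap.grid.ny},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_ratemap(path) -> RateMap:
    path = Path(path)
    rate = np.load(path.with_suffix(".npz"))["rate"]
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = MapGrid(**meta["grid"])
    return RateMap(grid=grid, rate=rate, method=meta.get("method", ""),
                   params=meta.get("params", {}))


def export_ratemap_csv(rmap: RateMap, path) -> Path:
    """Rate grid as CSV (rows = x bins, columns = y bins, empty = missing)."""
    path = Path(path)
    g = rmap.grid
    with open(path, "w") as fh:
        fh.write(f"# rate map ({rmap.method}), Hz; x0={g.x0} y0={g.y0} h={g.h} mm\n")
        pd.DataFrame(rmap.rate).to_csv(fh, index=False, float_format="%.17g")
    return path


def save_cell(cell: PlaceCellModel, path) -> Path:
    """Probability grid as .npz plus field parameters in a JSON sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), prob_map=cell.prob_map)
    sidecar = {
        "mean_rate": cell.mean_rate,
        "fields": [asdict(f) for f in cell.fields],
        "arena": asdict(cell.arena),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_cell(path) -> PlaceCellModel:
    path = Path(path)
    prob = np.load(path.with_suffix(".npz"))["prob_map"]
    meta = json.loads(path.with_suffix(".json").read_text())
    fields = tuple(
        FieldParams(tuple(f["centroid"]), f["var_x"], f["var_y"], f["cov_xy"])
        for f in meta["fields"]
    )
    return PlaceCellModel(fields=fields, prob_map=prob,
                          mean_rate=meta["mean_rate"],
                          arena=ArenaSpec(**meta["arena"]))
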