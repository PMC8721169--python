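"""Serialization of simulation results to plain-text files.

All numeric outputs are CSV (grids are small and inspectability matters);
cell coordinates are written as 0-based ``(row, col)`` offset pairs in the
odd-r convention.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SimulationConfig, SimulationResult
from .kinetics import SPECIES
from .patterns import summarize


def events_frame(result: SimulationResult) -> pd.DataFrame:
    return pd.DataFrame(
        [{"time": e.time, "row": e.cell.row, "col": e.cell.col,
          "direction": e.direction, "new_logic_value": e.new_logic_value}
         for e in result.events],
        columns=["time", "row", "col", "direction", "new_logic_value"])


def trajectories_frame(result: SimulationResult) -> pd.DataFrame:
    """Long-format epoch-boundary trajectories: time, row, col, species, value."""
    grid = result.grid
    n_t = result.times.size
    rows = np.repeat(np.arange(grid.n_cells) // grid.n_cols, len(SPECIES))
    cols = np.repeat(np.arange(grid.n_cells) % grid.n_cols, len(SPECIES))
    species = np.tile(np.array(SPECIES), grid.n_cells)
    frames = []
    for i in range(n_t):
        frames.append(pd.DataFrame({
            "time": np.full(grid.n_cells * len(SPECIES), result.times[i]),
            "row": rows, "col": cols, "species": species,
            "value": result.states[i].reshape(-1)}))
    return pd.concat(frames, ignore_index=True)


def write_results(result: SimulationResult, outdir: str | Path,
                  write_trajectories: bool = True) -> dict[str, Path]:
    """Write the standard file set for one run; returns the paths written.

    Emits ``events.csv``, one ``delta_<time>.csv`` per snapshot,
    ``logic_final.csv``, ``trajectories.csv`` (long format, optional) and
    ``summary.json``, plus a normalized provenance copy of the config
    (``config_used.yaml``).
    """
    from .config import save_config  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    path = outdir / "events.csv"
    events_frame(result).to_csv(path, index=False)
    written["events"] = path

    for time, delta in sorted(result.snapshots.items()):
        path = outdir / f"delta_{time:.6g}.csv"
        np.savetxt(path, delta, delimiter=",", fmt="%.17g")
        written[f"delta_{time:.6g}"] = path

    path = outdir / "logic_final.csv"
    np.savetxt(path, result.final_logic, delimiter=",", fmt="%d")
    written["logic_final"] = path

    if write_trajectories:
        path = outdir / "trajectories.csv"
        trajectories_frame(result).to_csv(path, index=False,
                                          float_format="%.17g")
        written["trajectories"] = path

    summary = summarize(result.final_logic, result.grid, result.config.rule)
    path = outdir / "summary.json"
    payload = {
        "termination": result.termination,
        "final_time_hours": result.final_time,
        "n_events": len(result.events),
        "n_epochs": int(result.times.size - 1),
        **{k: (None if isinstance(v, float) and not np.isfinite(v) else v)
           for k, v in dataclasses.asdict(summary).items()},
    }
    path.write_text(json.dumps(payload, indent=2))
    written["summary"] = path

    path = outdir / "config_used.yaml"
    save_config(result.config, path)
    written["config"] = path
    return written


def read_trajectories(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
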