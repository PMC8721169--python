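"""Hexagon-tiling rendering of grid snapshots."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib
matplotlib.use("Agg")  # headless, deterministic backend
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import PatchCollection
from matplotlib.patches import RegularPolygon

from .hexgrid import GridSpec


def render_grid(snapshot: np.ndarray, grid: GridSpec, path: str | Path,
                color_scale: tuple[float, float] | None = None,
                cmap: str = "viridis", label: str = "Delta (a.u.)") -> Path:
    """Render a concentration matrix as a pointy-top hexagon tiling (PNG).

    Odd rows are offset half a cell to the right (odd-r convention); the
    color bar maps concentration to color.  Deterministic given inputs and
    backend settings.
    """
    snapshot = np.asarray(snapshot, dtype=float)
    if snapshot.shape != (grid.n_rows, grid.n_cols):
        raise ValueError(f"snapshot shape {snapshot.shape} does not match "
                         f"grid {grid.n_rows}x{grid.n_cols}")
    vmin, vmax = color_scale if color_scale is not None else \
        (float(snapshot.min()), float(snapshot.max()) or 1.0)
    dy = math.sqrt(3.0) / 2.0
    patches = []
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            x = col + 0.5 * (row % 2)
            y = -row * dy
            patches.append(RegularPolygon((x, y), numVertices=6,
                                          radius=1 / math.sqrt(3.0),
                                          orientation=0.0))
    fig, ax = plt.subplots(figsize=(max(3.0, grid.n_cols * 0.35),
                                    max(3.0, grid.n_rows * 0.35)))
    coll = PatchCollection(patches, cmap=cmap, edgecolor="white",
                           linewidth=0.3)
    coll.set_array(snapshot.reshape(-1))
    coll.set_clim(vmin, vmax)
    ax.add_collection(coll)
    ax.set_xlim(-1, grid.n_cols + 1)
    ax.set_ylim(-(grid.n_rows + 1) * dy, 1)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.colorbar(coll, ax=ax, shrink=0.8, label=label)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight",
                metadata={"Software": "hexnotch"})
    plt.close(fig)
    return path
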