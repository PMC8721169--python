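"""Logic layer: binarization and neighborhood quorum rules.

Cell-cell communication is coarse-grained: each cell's Delta concentration
is thresholded into a binary logic value ``C_i`` (the grid of these values
is the logic matrix), and each cell's ligand input ``DE`` is a quorum
function of the logic values on a neighbor ring — ``DE = DEmax`` when at
least ``theta`` of the cells at hex distance ``dist`` are Delta-positive,
else 0.  A position-only field (a Wnt-like gradient) provides an input that
does not depend on other cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hexgrid import CellIndex, GridSpec, ring


@dataclass(frozen=True)
class LogicRule:
    """Quorum rule computing the ligand input of a cell.

    The neighborhood of a clause with distance ``d`` is the exact ring at
    hex distance ``d`` (6 cells at d=1, 12 at d=2, 18 at d=3 on large
    grids), not the filled disk.  The default rule has the single clause
    ``(dist, weight=1)``; additional weighted clauses over other rings can
    be supplied, in which case the weighted positive-neighbor count is
    compared against ``theta``.
    """

    dist: int = 1
    theta: int = 1
    DEmax: float = 2.0
    extra_clauses: tuple[tuple[int, float], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.dist < 1:
            raise ValueError("rule distance must be >= 1")
        if self.theta < 1:
            raise ValueError("rule quorum theta must be >= 1")
        if self.DEmax < 0:
            raise ValueError("DEmax must be non-negative")
        object.__setattr__(self, "extra_clauses",
                           tuple((int(d), float(w))
                                 for d, w in self.extra_clauses))
        for d, _ in self.extra_clauses:
            if d < 1:
                raise ValueError("clause distances must be >= 1")

    @property
    def clauses(self) -> tuple[tuple[int, float], ...]:
        return ((self.dist, 1.0),) + self.extra_clauses

    def check_feasible(self, grid: GridSpec) -> None:
        """Warn when the quorum exceeds the largest attainable score."""
        best = 0.0
        for d, w in self.clauses:
            sizes = [len(ring(grid, c, d)) for c in grid.cells()]
            best += w * max(sizes, default=0)
        if self.theta > best:
            warnings.warn(
                f"quorum theta={self.theta} exceeds the maximum attainable "
                f"weighted neighbor count {best:g} on this grid; the rule "
                "can never fire", stacklevel=2)


def binarize(delta_values: np.ndarray, Th: float) -> np.ndarray:
    """Entrywise logic value: 1 where ``D >= Th``, 0 where ``D < Th``.

    The boundary ``D == Th`` maps to 1.  Idempotent on already-binary
    fields whenever ``Th <= 1``.
    """
    if not Th > 0:
        raise ValueError("threshold Th must be positive")
    delta_values = np.asarray(delta_values)
    return (delta_values >= Th).astype(np.int8)


def dependent_input(V: np.ndarray, cell: CellIndex, rule: LogicRule,
                    grid: GridSpec) -> float:
    """Ligand input of one cell from the logic matrix ``V``.

    Returns ``rule.DEmax`` when the (weighted) number of positive cells on
    the rule's neighbor ring(s) reaches the quorum ``theta``, else 0.  The
    rule is a threshold function of the neighbor sum, hence monotone in
    ``V`` and invariant under permutations of the neighbors.
    """
    V = np.asarray(V)
    if V.shape != (grid.n_rows, grid.n_cols):
        raise ValueError(f"logic matrix shape {V.shape} does not match "
                         f"grid {grid.n_rows}x{grid.n_cols}")
    score = 0.0
    for d, w in rule.clauses:
        score += w * sum(int(V[n.row, n.col]) for n in ring(grid, cell, d))
    return rule.DEmax if score >= rule.theta else 0.0


def neighbor_index_table(grid: GridSpec, dist: int) -> list[np.ndarray]:
    """Flat-index neighbor lists of every cell's ring at ``dist``.

    Precomputed once per run so the per-epoch input refresh is pure array
    arithmetic.
    """
    return [np.fromiter((grid.index(n) for n in ring(grid, c, dist)),
                        dtype=np.intp)
            for c in grid.cells()]


def dependent_inputs_all(V: np.ndarray, rule: LogicRule, grid: GridSpec,
                         tables: dict[int, list[np.ndarray]] | None = None,
                         ) -> np.ndarray:
    """Vectorized ``dependent_input`` for every cell; returns shape (n_cells,)."""
    V = np.asarray(V)
    if V.shape != (grid.n_rows, grid.n_cols):
        raise ValueError(f"logic matrix shape {V.shape} does not match "
                         f"grid {grid.n_rows}x{grid.n_cols}")
    flat = V.reshape(-1)
    score = np.zeros(grid.n_cells)
    for d, w in rule.clauses:
        table = (tables or {}).get(d)
        if table is None:
            table = neighbor_index_table(grid, d)
        score += w * np.array([flat[idx].sum() for idx in table], dtype=float)
    return np.where(score >= rule.theta, rule.DEmax, 0.0)


def wnt_field(grid: GridSpec, Wmax: float, axis: str = "row") -> np.ndarray:
    """Static positional input field: linear gradient across the grid.

    Along the default ``row`` axis the field is 0 in the top row and
    ``Wmax`` in the bottom row, varying linearly in the row index; ``col``
    gives the transposed arrangement.  A degenerate grid (a single row for
    the row axis) has no direction to grade along and yields a zero field
    with a warning.
    """
    if Wmax < 0:
        raise ValueError("Wmax must be non-negative")
    if axis not in ("row", "col"):
        raise ValueError(f"unknown gradient axis {axis!r}")
    n = grid.n_rows if axis == "row" else grid.n_cols
    if n == 1:
        warnings.warn("gradient axis has a single cell; the positional "
                      "field degenerates to zero", stacklevel=2)
        return np.zeros((grid.n_rows, grid.n_cols))
    profile = Wmax * np.arange(n) / (n - 1)
    if axis == "row":
        return np.tile(profile[:, None], (1, grid.n_cols))
    return np.tile(profile[None, :], (grid.n_rows, 1))
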