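"""Hexagonal-lattice geometry for tissue grids.

Cells live on a two-dimensional hexagonal lattice addressed externally by
``(row, col)`` offset coordinates in the "odd-r" convention (odd rows are
shifted half a cell to the right, pointy-top hexagons).  Internally all
geometry is done in axial coordinates ``(q, r)``, which make neighbor
enumeration and graph distance O(1) per cell.

Three boundary modes are supported:

``bounded``
    No wrapping; border cells simply have fewer neighbors.
``cylindrical``
    The lateral (column) borders are glued, folding the sheet along the
    vertical axis into a cylinder.  This is the mode used for epithelial
    patterning scenarios, where it removes lateral edge artifacts.
``toroidal``
    Both pairs of borders are glued.  Row wrapping on a hex lattice only
    preserves adjacency when the number of rows is even, so toroidal grids
    require an even ``n_rows``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator, NamedTuple


class GridAddressError(IndexError):
    """Raised when a cell index does not address a cell of the grid."""


class Boundary(str, Enum):
    BOUNDED = "bounded"
    CYLINDRICAL = "cylindrical"
    TOROIDAL = "toroidal"


class CellIndex(NamedTuple):
    """External (row, col) offset address of a cell (odd-r convention)."""

    row: int
    col: int


# Axial-coordinate steps to the six nearest neighbors of a hex cell.
_AXIAL_DIRECTIONS = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))


@dataclass(frozen=True)
class GridSpec:
    """Dimensions and boundary mode of a hexagonal cell grid."""

    n_rows: int
    n_cols: int
    boundary: Boundary = Boundary.CYLINDRICAL

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive "
                             f"(got {self.n_rows}x{self.n_cols})")
        boundary = Boundary(self.boundary)
        object.__setattr__(self, "boundary", boundary)
        if boundary is Boundary.TOROIDAL and self.n_rows % 2 != 0:
            raise ValueError(
                "toroidal grids require an even number of rows: wrapping an "
                "odd number of hex rows breaks adjacency consistency "
                f"(got n_rows={self.n_rows})")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def wraps_cols(self) -> bool:
        return self.boundary in (Boundary.CYLINDRICAL, Boundary.TOROIDAL)

    @property
    def wraps_rows(self) -> bool:
        return self.boundary is Boundary.TOROIDAL

    def validate_cell(self, cell: CellIndex) -> CellIndex:
        row, col = cell
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise GridAddressError(
                f"cell ({row}, {col}) is outside the "
                f"{self.n_rows}x{self.n_cols} grid")
        return CellIndex(int(row), int(col))

    def index(self, cell: CellIndex) -> int:
        """Row-major flat index of a cell (used for stacked state arrays)."""
        row, col = self.validate_cell(cell)
        return row * self.n_cols + col

    def cell(self, flat_index: int) -> CellIndex:
        if not 0 <= flat_index < self.n_cells:
            raise GridAddressError(f"flat index {flat_index} out of range")
        return CellIndex(flat_index // self.n_cols, flat_index % self.n_cols)

    def cells(self) -> Iterator[CellIndex]:
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                yield CellIndex(row, col)


def offset_to_axial(row: int, col: int) -> tuple[int, int]:
    """odd-r offset -> axial; bijective on the integer lattice."""
    return col - (row - (row & 1)) // 2, row


def axial_to_offset(q: int, r: int) -> tuple[int, int]:
    """axial -> odd-r offset; inverse of :func:`offset_to_axial`."""
    return r, q + (r - (r & 1)) // 2


def _axial_length(q: int, r: int) -> int:
    """Hex graph distance from the origin to axial point (q, r)."""
    return (abs(q) + abs(r) + abs(q + r)) // 2


def wrap_lattice_point(grid: GridSpec, q: int, r: int) -> CellIndex | None:
    """Map an arbitrary axial lattice point onto the grid.

    Returns the canonical ``CellIndex`` after applying the grid's wrapping,
    or ``None`` when the point falls outside a non-wrapped border.
    """
    n_rows, n_cols = grid.n_rows, grid.n_cols
    if grid.wraps_rows:
        # Identity translation of the wrapped lattice along rows is
        # (q, r) ~ (q + n_rows/2, r - n_rows); reduce r into [0, n_rows).
        k = r // n_rows
        q += k * (n_rows // 2)
        r -= k * n_rows
    elif not 0 <= r < n_rows:
        return None
    row, col = axial_to_offset(q, r)
    if grid.wraps_cols:
        col %= n_cols
    elif not 0 <= col < n_cols:
        return None
    return CellIndex(row, col)


def hex_distance(grid: GridSpec, a: CellIndex, b: CellIndex) -> int:
    """Minimal number of adjacent-cell steps between two grid cells.

    On wrapped grids the minimum is taken over all wrapped images of ``b``.
    """
    a = grid.validate_cell(a)
    b = grid.validate_cell(b)
    qa, ra = offset_to_axial(*a)
    qb, rb = offset_to_axial(*b)
    dq, dr = qb - qa, rb - ra
    col_shifts = (-1, 0, 1) if grid.wraps_cols else (0,)
    row_shifts = (-1, 0, 1) if grid.wraps_rows else (0,)
    half_rows = grid.n_rows // 2
    best = None
    for j in row_shifts:
        for i in col_shifts:
            d = _axial_length(dq + i * grid.n_cols + j * half_rows,
                              dr - j * grid.n_rows)
            if best is None or d < best:
                best = d
    return best


def ring(grid: GridSpec, cell: CellIndex, dist: int) -> set[CellIndex]:
    """All grid cells at exact hexagonal graph distance ``dist`` from a cell.

    Boundary wrapping is applied before measuring distance; on bounded grids
    off-grid lattice positions are dropped.  On small wrapped grids two
    lattice positions of the ring can alias to the same grid cell — the
    result is deduplicated, and aliased cells whose wrapped distance is
    shorter than ``dist`` are excluded, so membership always agrees with
    :func:`hex_distance`.
    """
    cell = grid.validate_cell(cell)
    if dist < 0:
        raise ValueError("dist must be non-negative")
    if dist == 0:
        return {cell}
    qc, rc = offset_to_axial(*cell)
    # Walk the lattice ring of radius `dist` (6*dist lattice points).
    q = qc + _AXIAL_DIRECTIONS[4][0] * dist
    r = rc + _AXIAL_DIRECTIONS[4][1] * dist
    members: set[CellIndex] = set()
    for step_q, step_r in _AXIAL_DIRECTIONS:
        for _ in range(dist):
            wrapped = wrap_lattice_point(grid, q, r)
            if wrapped is not None and hex_distance(grid, cell, wrapped) == dist:
                members.add(wrapped)
            q += step_q
            r += step_r
    return members
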