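"""Quantitative descriptors of terminal grid patterns.

A completed lateral-inhibition pattern ("salt-and-pepper") is
operationalized as a maximal independent set of the neighbor graph defined
by the logic rule: no Delta-positive cell sees a quorum of positive
neighbors on its ring, and every Delta-negative cell does see one (unless a
positional field is separately pinning its fate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hexgrid import CellIndex, GridSpec, hex_distance, ring
from .logic import LogicRule


@dataclass(frozen=True)
class PatternSummary:
    """Headline statistics of one binary grid pattern."""

    n_positive: int
    fraction_positive: float
    is_valid_lateral_inhibition: bool | None
    min_pairwise_distance_between_positives: float  # inf when < 2 positives


@dataclass(frozen=True)
class Violation:
    """One cell breaking the equilibrium-pattern conditions."""

    cell: CellIndex
    kind: str        # "positive_overinhibited" | "negative_uninhibited"
    positives_on_ring: int


def check_lateral_inhibition_equilibrium(
        logic: np.ndarray, rule: LogicRule, grid: GridSpec,
        exempt: np.ndarray | None = None,
) -> tuple[bool, list[Violation]]:
    """Is this logic matrix a completed lateral-inhibition pattern?

    True iff (a) every positive cell's ring at ``rule.dist`` holds fewer
    than ``rule.theta`` positives (it receives no inhibitory quorum), and
    (b) every negative cell's ring holds at least ``rule.theta`` positives
    (something keeps it off).  Cells flagged in ``exempt`` — e.g. cells
    whose fate is pinned by a positional field rather than by neighbors —
    are excused from condition (b).  Violations are enumerated per cell.
    """
    logic = np.asarray(logic)
    if logic.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("logic matrix shape does not match grid")
    violations: list[Violation] = []
    for cell in grid.cells():
        on_ring = sum(int(logic[n.row, n.col])
                      for n in ring(grid, cell, rule.dist))
        if logic[cell.row, cell.col]:
            if on_ring >= rule.theta:
                violations.append(Violation(cell, "positive_overinhibited",
                                            on_ring))
        else:
            if on_ring < rule.theta and not (
                    exempt is not None and exempt[cell.row, cell.col]):
                violations.append(Violation(cell, "negative_uninhibited",
                                            on_ring))
    return not violations, violations


def summarize(logic: np.ndarray, grid: GridSpec,
              rule: LogicRule | None = None) -> PatternSummary:
    """Counts and spacing of Delta-positive cells in a binary grid.

    The minimum pairwise distance between positives uses the grid's own
    boundary mode; with fewer than two positives it is reported as ``inf``.
    When a rule is supplied the maximal-independent-set validity flag is
    evaluated, otherwise it is ``None``.
    """
    logic = np.asarray(logic)
    if logic.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("logic matrix shape does not match grid")
    positives = [CellIndex(r, c) for r, c in zip(*np.nonzero(logic))]
    n_pos = len(positives)
    min_dist = math.inf
    for i in range(n_pos):
        for j in range(i + 1, n_pos):
            min_dist = min(min_dist,
                           hex_distance(grid, positives[i], positives[j]))
    valid = None
    if rule is not None:
        valid, _ = check_lateral_inhibition_equilibrium(logic, rule, grid)
    return PatternSummary(
        n_positive=n_pos,
        fraction_positive=n_pos / grid.n_cells,
        is_valid_lateral_inhibition=valid,
        min_pairwise_distance_between_positives=float(min_dist),
    )
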