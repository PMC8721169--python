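"""Event-driven co-simulation of the tissue grid.

Between threshold crossings every cell's ligand input ``DE`` is constant,
so the stacked per-cell ODE systems are mutually independent and advancing
them together as one flat system is exact (no operator splitting).  The
engine therefore loops over *event epochs*:

1. binarize the current Delta field into the logic matrix,
2. evaluate every cell's ``DE`` with the quorum rule,
3. integrate the whole grid under those frozen inputs until the earliest
   crossing of the quantization threshold ``Th`` by any cell's Delta,
4. commit the crossing(s) as events and repeat,

until either no event occurs for ``equilibrium_window`` hours and the grid
is stationary (termination ``equilibrium``), or the time budget ``t_max``
is exhausted (termination ``t_max``).  Event times carry the quantitative
time (hours) produced by the ODE layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import block_diag

from .hexgrid import CellIndex, GridSpec
from .kinetics import (DELTA_INDEX, SPECIES, KineticParams, rhs_array)
from .logic import (LogicRule, binarize, dependent_inputs_all,
                    neighbor_index_table)


class SimulationError(RuntimeError):
    """Integration failure, annotated with run context."""


#: Default per-species uniform initialization intervals (a.u.).  They span
#: the scale set by the model's stimulated/unstimulated steady states, with
#: the Hes arm started from clearly non-zero levels: cells enter the
#: simulation from a signaling-active context, so every cell's Delta is
#: transiently self-repressed before the neighborhood competition resolves.
DEFAULT_INIT_RANGES: dict[str, tuple[float, float]] = {
    "NC": (0.0, 3.5),
    "NN": (0.0, 8.5),
    "HNmRNA": (0.8, 2.0),
    "HCp": (1.5, 2.7),
    "HNp": (1.2, 2.2),
    "D": (0.0, 4.0),
}

#: Relative half-width of the hysteresis band around Th inside which a
#: cell's own event function stays disarmed, preventing zero-length epochs
#: at grazing contact.
HYSTERESIS_BAND = 1e-6

#: Relative proximity to Th within which co-crossing cells are committed in
#: the same epoch.
SIMULTANEITY_TOL = 1e-9

#: Equilibrium requires max|rhs| below this multiple of ktD at the end of
#: an event-free window.  The value sits above the residual floor that the
#: default solver tolerances leave in a fully converged state (~1e-5*ktD)
#: while still bounding the Delta drift per window to far less than any
#: threshold margin.
EQUILIBRIUM_RHS_TOL = 1e-4


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one tissue simulation."""

    grid: GridSpec
    rule: LogicRule = field(default_factory=LogicRule)
    params: KineticParams = field(default_factory=KineticParams)
    wnt: np.ndarray | None = None          # static positional field, grid shape
    init_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INIT_RANGES))
    seed: int = 0
    t_max: float = 300.0                   # hours
    equilibrium_window: float = 25.0       # hours
    snapshot_times: tuple[float, ...] = ()
    method: str = "RK45"                   # any solve_ivp method
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self) -> None:
        if self.t_max < 0:
            raise ValueError("t_max must be non-negative")
        if not self.equilibrium_window > 0:
            raise ValueError("equilibrium_window must be positive")
        for name in SPECIES:
            if name not in self.init_ranges:
                raise ValueError(f"init range missing for species {name}")
            low, high = self.init_ranges[name]
            if low < 0 or high < low:
                raise ValueError(
                    f"init range for {name} must satisfy 0 <= low <= high "
                    f"(got [{low}, {high}])")
        if self.wnt is not None:
            self.wnt = np.asarray(self.wnt, dtype=float)
            if self.wnt.shape != (self.grid.n_rows, self.grid.n_cols):
                raise ValueError("wnt field shape does not match grid")
            if np.any(self.wnt < 0):
                raise ValueError("wnt field must be non-negative")
        self.snapshot_times = tuple(float(t) for t in self.snapshot_times)


@dataclass(frozen=True)
class EventRecord:
    """One threshold crossing of one cell."""

    time: float
    cell: CellIndex
    direction: str            # "up" (Delta rose through Th) or "down"
    new_logic_value: int


@dataclass
class SimulationResult:
    """Full record of one run.

    ``times``/``states`` sample every epoch boundary (``states`` has shape
    ``(n_times, n_cells, 6)``); ``logic_history`` holds the logic matrix at
    the same instants.  ``snapshots`` maps requested times to Delta
    concentration matrices of grid shape.
    """

    config: SimulationConfig
    events: list[EventRecord]
    times: np.ndarray
    states: np.ndarray
    logic_history: np.ndarray
    snapshots: dict[float, np.ndarray]
    final_logic: np.ndarray
    termination: str          # "equilibrium" | "t_max" | "error"

    @property
    def grid(self) -> GridSpec:
        return self.config.grid

    @property
    def final_time(self) -> float:
        return float(self.times[-1])

    @property
    def final_delta(self) -> np.ndarray:
        return self.states[-1, :, DELTA_INDEX].reshape(
            self.grid.n_rows, self.grid.n_cols)

    def trajectory(self, cell: CellIndex) -> np.ndarray:
        """Epoch-boundary time series of one cell, shape (n_times, 6)."""
        return self.states[:, self.grid.index(cell), :]

    def positive_counts(self) -> np.ndarray:
        """Number of Delta-positive cells at each recorded instant."""
        return self.logic_history.sum(axis=(1, 2))


def initialize(config: SimulationConfig) -> np.ndarray:
    """Random initial grid state, shape ``(n_cells, 6)``.

    Every species of every cell is drawn independently and uniformly from
    its configured range; reproducible given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.grid.n_cells
    columns = [rng.uniform(*config.init_ranges[name], size=n)
               for name in SPECIES]
    return np.column_stack(columns)


def _make_flat_rhs(n_cells: int, DE: np.ndarray, W: np.ndarray | float,
                   p: KineticParams) -> Callable:
    def f(t, y):
        return rhs_array(y.reshape(n_cells, 6), DE, W, p).reshape(-1)
    return f


def advance_to_next_event(states: np.ndarray, logic: np.ndarray,
                          DE: np.ndarray, t0: float, t_end: float,
                          config: SimulationConfig,
                          ) -> tuple[np.ndarray, list[tuple[int, str]], float]:
    """Integrate the grid under frozen inputs until the earliest crossing.

    Returns ``(states_at_t_star, crossings, t_star)`` where ``crossings``
    lists ``(flat_cell_index, direction)`` pairs; it is empty when no cell
    crosses ``Th`` before ``t_end`` (then ``t_star == t_end``).

    Each cell's crossing is detected relative to the side its current
    *logic* value puts it on.  A cell starting inside the hysteresis band
    around ``Th`` (e.g. one committed in the previous epoch) only fires
    once its Delta moves beyond the band on the opposite side, which
    suppresses zero-length chattering epochs at grazing contact without
    ever letting a genuine switch pass unobserved.  All cells on their
    event surface within the simultaneity tolerance at ``t_star`` are
    committed together.
    """
    p = config.params
    n_cells = config.grid.n_cells
    W = config.wnt.reshape(-1) if config.wnt is not None else 0.0
    y0 = np.asarray(states, dtype=float).reshape(-1)
    if t_end <= t0:
        return states.copy(), [], t0

    D0 = y0[DELTA_INDEX::6]
    logic_flat = np.asarray(logic).reshape(-1)
    side = np.where(logic_flat > 0, 1.0, -1.0)
    band = HYSTERESIS_BAND * p.Th
    offset = np.where(np.abs(D0 - p.Th) <= band, band, 0.0)

    def surface(d: np.ndarray) -> np.ndarray:
        # Negative while each cell stays on its logical side; zero at the
        # (band-shifted) crossing.
        return (d - p.Th) * (-side) - offset

    def crossing(t, y):
        return np.max(surface(y[DELTA_INDEX::6]))

    crossing.terminal = True
    crossing.direction = 1.0

    kwargs: dict = {}
    if config.method in ("BDF", "Radau"):
        # The Jacobian is block diagonal: cells only couple through the
        # frozen inputs.  Implicit solvers exploit the sparsity.
        kwargs["jac_sparsity"] = block_diag(
            [np.ones((6, 6))] * n_cells, format="csr")

    sol = solve_ivp(_make_flat_rhs(n_cells, DE, W, p), (t0, t_end), y0,
                    method=config.method, rtol=config.rtol, atol=config.atol,
                    events=[crossing], dense_output=True, **kwargs)
    if not sol.success:
        raise SimulationError(
            f"grid integration failed at t={sol.t[-1]:.6g} h: {sol.message}")

    if sol.status == 1 and sol.t_events[0].size:
        t_star = float(sol.t_events[0][0])
        y_star = sol.y_events[0][0]
        h_star = surface(y_star[DELTA_INDEX::6])
        crossers = np.where(h_star >= -SIMULTANEITY_TOL * p.Th)[0]
        if crossers.size == 0:
            crossers = np.array([int(np.argmax(h_star))])
        crossings = [(int(i), "up" if side[i] < 0 else "down")
                     for i in sorted(crossers)]
        return y_star.reshape(n_cells, 6), crossings, t_star

    return sol.y[:, -1].reshape(n_cells, 6), [], float(sol.t[-1])


def run(config: SimulationConfig,
        progress: Callable[[int, float, int], None] | None = None,
        initial_states: np.ndarray | None = None,
        ) -> SimulationResult:
    """Simulate one tissue until pattern equilibrium or the time budget.

    ``progress``, if given, is called after each epoch with
    ``(epoch_index, time, n_events_committed)``.  ``initial_states``
    (shape ``(n_cells, 6)``) overrides the seeded random initialization.
    """
    grid = config.grid
    p = config.params
    shape = (grid.n_rows, grid.n_cols)
    tables = {d: neighbor_index_table(grid, d)
              for d, _ in config.rule.clauses}
    config.rule.check_feasible(grid)

    if initial_states is not None:
        states = np.array(initial_states, dtype=float)
        if states.shape != (grid.n_cells, 6):
            raise ValueError("initial_states must have shape (n_cells, 6)")
        if np.any(states < 0):
            raise ValueError("initial states must be non-negative")
    else:
        states = initialize(config)
    t = 0.0
    logic = binarize(states[:, DELTA_INDEX].reshape(shape), p.Th)
    events: list[EventRecord] = []
    times = [0.0]
    state_log = [states.copy()]
    logic_log = [logic.copy()]
    wanted_snaps = sorted(set(config.snapshot_times))
    snapshots: dict[float, np.ndarray] = {}

    def snap(time: float, state_matrix: np.ndarray) -> None:
        snapshots[time] = state_matrix[:, DELTA_INDEX].reshape(shape).copy()

    snap(0.0, states)
    termination = "t_max"
    epoch = 0
    last_event_t = 0.0
    W = config.wnt.reshape(-1) if config.wnt is not None else 0.0

    while t < config.t_max:
        DE = dependent_inputs_all(logic, config.rule, grid, tables)
        horizon = min(last_event_t + config.equilibrium_window, config.t_max)
        if horizon <= t:
            horizon = min(t + config.equilibrium_window, config.t_max)
        new_states, crossings, t_star = advance_to_next_event(
            states, logic, DE, t, horizon, config)

        # Record requested snapshot times passed during this epoch (taken
        # from the committed epoch-boundary state closest from above).
        for ts in wanted_snaps:
            if t < ts <= t_star and ts not in snapshots:
                snap(ts, new_states)

        states = new_states
        t = t_star

        # Refresh the logic matrix from the new Delta field.  Cells inside
        # the hysteresis band sit numerically on the threshold, where raw
        # binarization is meaningless: they keep their logical side until
        # a committed crossing flips it.
        delta = states[:, DELTA_INDEX].reshape(shape)
        new_logic = binarize(delta, p.Th)
        in_band = np.abs(delta - p.Th) <= HYSTERESIS_BAND * p.Th
        new_logic[in_band] = logic[in_band]
        for idx, direction in crossings:
            cell = grid.cell(idx)
            new_logic[cell.row, cell.col] = 1 if direction == "up" else 0
        logic = new_logic

        if crossings:
            for idx, direction in crossings:
                events.append(EventRecord(
                    time=t, cell=grid.cell(idx), direction=direction,
                    new_logic_value=1 if direction == "up" else 0))
            last_event_t = t
        else:
            derivs = rhs_array(states, DE, W, p)
            if np.max(np.abs(derivs)) < EQUILIBRIUM_RHS_TOL * p.ktD:
                termination = "equilibrium"
                times.append(t)
                state_log.append(states.copy())
                logic_log.append(logic.copy())
                if progress is not None:
                    progress(epoch, t, 0)
                break

        times.append(t)
        state_log.append(states.copy())
        logic_log.append(logic.copy())
        if progress is not None:
            progress(epoch, t, len(crossings))
        epoch += 1

    snap(float(t), states)
    final_logic = binarize(states[:, DELTA_INDEX].reshape(shape), p.Th)
    return SimulationResult(
        config=config,
        events=events,
        times=np.array(times),
        states=np.stack(state_log),
        logic_history=np.stack(logic_log),
        snapshots=snapshots,
        final_logic=final_logic,
        termination=termination,
    )
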