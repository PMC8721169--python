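"""Intracellular Delta-Notch signaling cascade (six-species ODE model).

A cell has two compartments, cytoplasm (volume ``VC``) and nucleus (volume
``VN``).  Binding of external Delta ligand ``DE`` to free membrane Notch
cleaves the Notch intracellular domain (NICD) into the cytoplasm (``NC``);
NICD enters the nucleus (``NN``) by passive and active transport and drives
Hes transcription through an activating Hill function.  Hes mRNA
(``HNmRNA``) is translated into cytoplasmic Hes protein (``HCp``), which
equilibrates with the nuclear pool (``HNp``); nuclear Hes represses Delta
transcription through a repressing Hill function, closing the
lateral-inhibition feedback loop.  Delta mRNA (``D``) is the cell's readout:
translation and maturation are collapsed into it, adding only a delay that
the model does not resolve.

Membrane Notch is conserved: with total Notch ``Ntot`` held constant the
free receptor pool is the algebraic remainder

    Notch_free = Ntot - NC - NN * VN / VC.

An optional positional input ``W`` (a Wnt-like morphogen) inhibits the
transcriptional activity of nuclear NICD through a repressing Hill factor
multiplying the Hes transcription term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
from scipy.integrate import solve_ivp

#: Canonical ordering of the state variables in array form.
SPECIES = ("NC", "NN", "HNmRNA", "HCp", "HNp", "D")

#: Index of Delta in the state vector (the binarized readout species).
DELTA_INDEX = SPECIES.index("D")


@dataclass(frozen=True)
class KineticParams:
    """Rate constants, volumes, totals and thresholds of the cascade.

    Units: concentrations are in arbitrary concentration units (a.u.),
    volumes in arbitrary volume units, time in hours.  The defaults are an
    artifact-chosen reference set (they are not measured values): they were
    picked so that the quantization threshold ``Th`` lies well between the
    ligand-repressed and unstimulated Delta steady states and the two-cell
    system is bistable, which is the operating regime of lateral
    inhibition.  All of them can be overridden from the run config.
    """

    VC: float = 1.0        # cytoplasmic volume
    VN: float = 0.5        # nuclear volume
    Ntot: float = 10.0     # total membrane Notch (conserved pool, a.u.)
    kcl: float = 2.0       # NICD cleavage rate per unit ligand (1/(a.u. h))
    ktrP: float = 2.0      # passive nuclear transport rate (vol/h)
    ktrA: float = 4.0      # active nuclear import rate (vol/h)
    muN: float = 1.0       # NICD degradation rate (1/h)
    ktH: float = 4.0       # maximal Hes transcription rate (a.u./h)
    KH: float = 2.0        # NICD half-saturation of Hes transcription (a.u.)
    muHmRNA: float = 2.0   # Hes mRNA degradation rate (1/h)
    kHp: float = 4.0       # Hes translation rate (1/h)
    muHp: float = 1.0      # Hes protein degradation rate (1/h)
    ktD: float = 8.0       # maximal Delta transcription rate (a.u./h)
    KD: float = 0.5        # Hes half-repression of Delta transcription (a.u.)
    muD: float = 2.0       # Delta degradation rate (1/h)
    DEmax: float = 2.0     # amplitude of the binary ligand input (a.u.)
    Th: float = 2.0        # Delta quantization threshold (a.u.)
    nH: int = 2            # Hill exponent of both cascade Hill terms
    KW: float = 4.0        # Wnt half-inhibition of NICD activity (a.u.)
    nW: int = 2            # Hill exponent of the Wnt inhibition factor

    def __post_init__(self) -> None:
        for name in ("VC", "VN", "Ntot", "kcl", "ktrP", "ktrA", "muN", "ktH",
                     "KH", "muHmRNA", "kHp", "muHp", "ktD", "KD", "muD",
                     "DEmax", "Th", "KW"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"kinetic parameter {name} must be strictly "
                                 f"positive (got {value!r})")
        if self.nH < 1 or self.nW < 1:
            raise ValueError("Hill exponents must be >= 1")
        if not self.Th < self.ktD / self.muD:
            raise ValueError(
                "Th must lie below the unstimulated Delta steady state "
                f"ktD/muD = {self.ktD / self.muD:g} (got Th={self.Th:g}); "
                "otherwise no threshold crossing can ever occur")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class CellState:
    """The six concentration variables of one cell (a.u.)."""

    NC: float = 0.0
    NN: float = 0.0
    HNmRNA: float = 0.0
    HCp: float = 0.0
    HNp: float = 0.0
    D: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "CellState":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(SPECIES),):
            raise ValueError(f"expected {len(SPECIES)} state values, "
                             f"got shape {values.shape}")
        return cls(**dict(zip(SPECIES, values.tolist())))


def notch_free(state: CellState | np.ndarray, p: KineticParams):
    """Free membrane Notch: ``Ntot - NC - NN * VN / VC``.

    Accepts a :class:`CellState` or an array whose last axis is the species
    axis.  The value is returned as written (it can transiently dip slightly
    below zero at coarse solver tolerance); the cleavage flux in :func:`rhs`
    clips it at zero so a negative excursion cannot fabricate Notch.
    """
    if isinstance(state, CellState):
        return p.Ntot - state.NC - state.NN * (p.VN / p.VC)
    state = np.asarray(state, dtype=float)
    return p.Ntot - state[..., 0] - state[..., 1] * (p.VN / p.VC)


def wnt_factor(W, p: KineticParams):
    """Repression Hill factor on NICD transcriptional activity.

    Equals 1 with no inhibitor and decreases strictly to 0 as ``W`` grows;
    half-inhibition at ``W = KW``.
    """
    W = np.asarray(W, dtype=float)
    factor = p.KW ** p.nW / (p.KW ** p.nW + W ** p.nW)
    return factor if factor.ndim else float(factor)


def rhs_array(states: np.ndarray, DE, W, p: KineticParams) -> np.ndarray:
    """Vectorized time-derivatives; ``states`` has shape ``(..., 6)``.

    ``DE`` and ``W`` broadcast against the leading axes.  This is the single
    implementation of the model equations used everywhere (single cells and
    stacked grids alike).
    """
    states = np.asarray(states, dtype=float)
    NC, NN, HNmRNA, HCp, HNp, D = np.moveaxis(states, -1, 0)
    DE = np.asarray(DE, dtype=float)
    free = np.maximum(notch_free(states, p), 0.0)
    n = p.nH
    dNC = (p.kcl * free * DE
           + (p.ktrP / p.VC) * (NN - NC)
           - (p.ktrA / p.VC) * NC
           - p.muN * NC)
    dNN = ((p.ktrP / p.VN) * (NC - NN)
           + (p.ktrA / p.VN) * NC
           - p.muN * NN)
    dHNmRNA = (wnt_factor(W, p) * p.ktH * NN ** n / (NN ** n + p.KH ** n)
               - p.muHmRNA * HNmRNA)
    dHCp = (p.kHp * HNmRNA * (p.VN / p.VC)
            + (p.ktrP / p.VC) * (HNp - HCp)
            - p.muHp * HCp)
    dHNp = (-(p.ktrP / p.VN) * (HNp - HCp)
            - p.muHp * HNp)
    dD = (p.ktD * p.KD ** n / (p.KD ** n + HNp ** n)
          - p.muD * D)
    return np.stack([dNC, dNN, dHNmRNA, dHCp, dHNp, dD], axis=-1)


def rhs(state: CellState, DE: float, W: float, p: KineticParams) -> CellState:
    """Time-derivative of one cell's state under ligand ``DE`` and Wnt ``W``.

    Raises ``ValueError`` on a negative state component — negative
    concentrations indicate an integration bug upstream, not a model state.
    """
    values = state.as_array()
    if np.any(values < 0):
        raise ValueError(f"negative concentration in state: {state}")
    if DE < 0 or W < 0:
        raise ValueError("inputs DE and W must be non-negative")
    return CellState.from_array(rhs_array(values, DE, W, p))


def steady_state_delta_unstimulated(p: KineticParams) -> float:
    """Delta fixed point of an unstimulated cell: ``ktD / muD``.

    With ``DE = 0`` the whole Notch/Hes arm decays to zero, the repression
    Hill factor tends to 1 and Delta relaxes to this value.
    """
    return p.ktD / p.muD


def delta_crossing_time_unstimulated(p: KineticParams) -> float:
    """Closed-form upward crossing time of ``Th`` from the zero state.

    With ``DE = 0`` and everything at zero, Delta follows the scalar linear
    ODE ``dD/dt = ktD - muD*D``, crossing the threshold at
    ``t* = -(1/muD) * ln(1 - Th*muD/ktD)``.
    """
    return -math.log(1.0 - p.Th * p.muD / p.ktD) / p.muD


@dataclass
class CellTrajectory:
    """Single-cell trajectory with threshold-crossing events.

    ``t`` is in hours; ``states`` has shape ``(len(t), 6)``.  ``crossings``
    lists ``(time, direction)`` pairs where direction is ``"up"`` when Delta
    rose through ``Th`` and ``"down"`` when it fell through it.
    """

    t: np.ndarray
    states: np.ndarray
    crossings: list[tuple[float, str]]

    @property
    def first_crossing(self) -> tuple[float, str] | None:
        return self.crossings[0] if self.crossings else None


def integrate_cell(state0: CellState | np.ndarray, DE: float, W: float,
                   p: KineticParams, t_span: tuple[float, float],
                   method: str = "LSODA", rtol: float = 1e-6,
                   atol: float = 1e-9, max_step: float = np.inf,
                   ) -> CellTrajectory:
    """Integrate one cell under constant inputs, reporting Th crossings.

    Both crossing directions of ``D = Th`` are located with the solver's
    event root-finder and reported in order.  Integration failures raise
    ``RuntimeError`` carrying the solver message.
    """
    y0 = state0.as_array() if isinstance(state0, CellState) else \
        np.asarray(state0, dtype=float)
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")

    def f(t, y):
        return rhs_array(y, DE, W, p)

    def cross_up(t, y):
        return y[DELTA_INDEX] - p.Th

    def cross_down(t, y):
        return y[DELTA_INDEX] - p.Th

    cross_up.direction = 1.0
    cross_down.direction = -1.0
    sol = solve_ivp(f, t_span, y0, method=method, rtol=rtol, atol=atol,
                    max_step=max_step, events=[cross_up, cross_down],
                    dense_output=True)
    if not sol.success:
        raise RuntimeError(f"cell integration failed: {sol.message}")
    crossings = sorted(
        [(float(t), "up") for t in sol.t_events[0]]
        + [(float(t), "down") for t in sol.t_events[1]])
    return CellTrajectory(t=sol.t, states=sol.y.T, crossings=crossings)
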