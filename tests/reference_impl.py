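"""Independent reference implementations used as test oracles.

Everything here is deliberately written from scratch, scalar and
unvectorized, sharing no code with the package: a second transcription of
the six model equations, and a monolithic brute-force tissue simulator
that integrates the fully stacked ODE system with per-cell scipy event
functions and manually switched inputs.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def rhs_reference(y, DE, W, p):
    """Scalar hand-transcription of the six cascade equations."""
    NC, NN, HNmRNA, HCp, HNp, D = y
    free = p.Ntot - NC - NN * p.VN / p.VC
    if free < 0.0:
        free = 0.0
    wnt = p.KW ** p.nW / (p.KW ** p.nW + W ** p.nW)
    dNC = (p.kcl * free * DE
           + p.ktrP / p.VC * (NN - NC)
           - p.ktrA / p.VC * NC
           - p.muN * NC)
    dNN = (p.ktrP / p.VN * (NC - NN)
           + p.ktrA / p.VN * NC
           - p.muN * NN)
    dHNmRNA = (wnt * p.ktH * NN ** p.nH / (NN ** p.nH + p.KH ** p.nH)
               - p.muHmRNA * HNmRNA)
    dHCp = (p.kHp * HNmRNA * p.VN / p.VC
            + p.ktrP / p.VC * (HNp - HCp)
            - p.muHp * HCp)
    dHNp = (-p.ktrP / p.VN * (HNp - HCp)
            - p.muHp * HNp)
    dD = (p.ktD * p.KD ** p.nH / (p.KD ** p.nH + HNp ** p.nH)
          - p.muD * D)
    return [dNC, dNN, dHNmRNA, dHCp, dHNp, dD]


def simulate_monolithic(neighbors, y0, p, theta, DEmax, t_max,
                        rtol=1e-10, atol=1e-12, max_events=10_000):
    """Brute-force hybrid simulation of a tiny tissue.

    ``neighbors`` is a hand-specified adjacency list of flat cell indices
    (ring at the rule distance).  Inputs are switched manually at each
    committed crossing; integration restarts with one terminal scipy event
    per cell, directed away from the cell's current logic side so a cell
    sitting exactly on the threshold cannot immediately re-fire.

    Returns ``(events, final_logic, final_states)`` where ``events`` is a
    list of ``(time, cell_index, direction)`` tuples.
    """
    n = len(neighbors)
    y = np.concatenate([np.asarray(s, dtype=float) for s in y0])
    logic = [1 if y[6 * i + 5] >= p.Th else 0 for i in range(n)]
    events = []
    t = 0.0

    def make_event(i, direction):
        def g(tt, yy):
            return yy[6 * i + 5] - p.Th
        g.terminal = True
        g.direction = direction
        return g

    def f(tt, yy):
        out = []
        for i in range(n):
            out.extend(rhs_reference(yy[6 * i:6 * i + 6], DE[i], 0.0, p))
        return out

    while t < t_max and len(events) < max_events:
        DE = [DEmax if sum(logic[j] for j in neighbors[i]) >= theta else 0.0
              for i in range(n)]
        evs = [make_event(i, -1.0 if logic[i] else 1.0) for i in range(n)]
        sol = solve_ivp(f, (t, t_max), y, method="LSODA", events=evs,
                        rtol=rtol, atol=atol)
        assert sol.success, sol.message
        crossed = [i for i in range(n) if sol.t_events[i].size]
        if not crossed:
            y = sol.y[:, -1]
            t = t_max
            break
        t_star = min(float(sol.t_events[i][0]) for i in crossed)
        # Commit every cell crossing within a tight simultaneity tolerance.
        committed = [i for i in crossed
                     if float(sol.t_events[i][0]) <= t_star * (1 + 1e-12)
                     + 1e-12]
        i0 = committed[0]
        y = sol.y_events[i0][0]
        for i in sorted(committed):
            direction = "down" if logic[i] else "up"
            logic[i] = 0 if logic[i] else 1
            events.append((t_star, i, direction))
        t = t_star
    return events, logic, y
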