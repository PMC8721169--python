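"""Event-driven engine: initialization, epochs, equilibria, oracle checks."""

import numpy as np
import pytest

import hexnotch as hx
from hexnotch.engine import SimulationConfig, initialize, run
from hexnotch.hexgrid import GridSpec
from hexnotch.kinetics import (DELTA_INDEX, KineticParams,
                               delta_crossing_time_unstimulated,
                               steady_state_delta_unstimulated)
from hexnotch.logic import LogicRule, binarize
from reference_impl import simulate_monolithic

TIGHT = dict(rtol=1e-10, atol=1e-12)


def single_cell_config(t_max=100.0, **kw):
    return SimulationConfig(grid=GridSpec(1, 1, "bounded"),
                            init_ranges={s: (0.0, 0.0) for s in hx.SPECIES},
                            t_max=t_max, **kw)


class TestInitialize:
    def test_degenerate_ranges_give_zero_grid(self, zero_ranges):
        cfg = SimulationConfig(grid=GridSpec(3, 3, "bounded"),
                               init_ranges=zero_ranges, seed=5)
        np.testing.assert_array_equal(initialize(cfg), np.zeros((9, 6)))

    def test_same_seed_reproduces_state(self):
        cfg = SimulationConfig(grid=GridSpec(6, 6, "cylindrical"), seed=17)
        np.testing.assert_array_equal(initialize(cfg), initialize(cfg))

    def test_uniform_sampling_mean(self):
        """Each species' sample mean sits within 3 SE of the range center."""
        ranges = {s: (0.0, 1.0) for s in hx.SPECIES}
        draws = []
        for seed in range(25):
            cfg = SimulationConfig(grid=GridSpec(20, 20, "cylindrical"),
                                   init_ranges=ranges, seed=seed)
            draws.append(initialize(cfg)[:, 0])
        draws = np.concatenate(draws)          # 10^4 uniform(0,1) samples
        se = np.sqrt(1 / 12 / draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_invalid_range_rejected(self):
        ranges = {s: (0.0, 1.0) for s in hx.SPECIES}
        ranges["D"] = (2.0, 1.0)
        with pytest.raises(ValueError, match="D"):
            SimulationConfig(grid=GridSpec(2, 2, "bounded"),
                             init_ranges=ranges)


class TestSingleCell:
    def test_isolated_cell_crosses_at_closed_form_time(self):
        """A 1x1 grid has no neighbors, so DE=0 always: the first event is
        the scalar linear ODE's threshold crossing."""
        res = run(single_cell_config(**TIGHT))
        p = res.config.params
        assert [e.direction for e in res.events] == ["up"]
        assert res.events[0].time == pytest.approx(
            delta_crossing_time_unstimulated(p), rel=1e-6)

    def test_isolated_cell_reaches_unstimulated_fixed_point(self):
        res = run(single_cell_config())
        p = res.config.params
        assert res.termination == "equilibrium"
        assert res.final_delta[0, 0] == pytest.approx(
            steady_state_delta_unstimulated(p), rel=1e-4)
        np.testing.assert_array_equal(res.final_logic, [[1]])

    def test_zero_time_budget(self):
        res = run(single_cell_config(t_max=0.0))
        assert res.termination == "t_max"
        assert res.events == []
        assert list(res.snapshots) == [0.0]
        assert res.times.size == 1

    def test_quiescent_grid_produces_no_event(self):
        cfg = single_cell_config(t_max=40.0)
        p = cfg.params
        s0 = np.zeros((1, 6))
        s0[0, DELTA_INDEX] = steady_state_delta_unstimulated(p)
        res = run(cfg, initial_states=s0)
        assert res.events == []
        assert res.termination == "equilibrium"


class TestSmallGridsAgainstMonolithicOracle:
    """The event-driven engine must reproduce a brute-force monolithic
    integration with manually switched inputs on tiny tissues."""

    def assert_agrees(self, cfg, y0, neighbors, t_max):
        res = run(cfg, initial_states=y0)
        ref_events, ref_logic, _ = simulate_monolithic(
            neighbors, list(y0), cfg.params, cfg.rule.theta, cfg.rule.DEmax,
            t_max)
        ours = [(e.time, cfg.grid.index(e.cell), e.direction)
                for e in res.events]
        assert len(ours) == len(ref_events)
        for (t1, c1, d1), (t2, c2, d2) in zip(ours, ref_events):
            assert t1 == pytest.approx(t2, rel=1e-6, abs=1e-9)
        # Near-simultaneous crossings may be reported in either order, so
        # compare (cell, direction) pairs cluster by cluster.
        def clusters(evts):
            out, cur, t_prev = [], [], None
            for t, c, d in evts:
                if cur and t - t_prev > 1e-6 * max(t, 1.0):
                    out.append(frozenset(cur))
                    cur = []
                cur.append((c, d))
                t_prev = t
            if cur:
                out.append(frozenset(cur))
            return out

        assert clusters(ours) == clusters(ref_events)
        np.testing.assert_array_equal(res.final_logic.reshape(-1),
                                      np.array(ref_logic))
        return res

    def test_asymmetric_pair_settles_one_positive_one_negative(self):
        cfg = SimulationConfig(grid=GridSpec(1, 2, "bounded"),
                               rule=LogicRule(dist=1, theta=1),
                               t_max=120.0, **TIGHT)
        p = cfg.params
        y0 = np.zeros((2, 6))
        y0[0, DELTA_INDEX] = 0.95 * steady_state_delta_unstimulated(p)
        res = self.assert_agrees(cfg, y0, [[1], [0]], 120.0)
        np.testing.assert_array_equal(res.final_logic, [[1, 0]])
        assert res.termination == "equilibrium"

    def test_random_two_by_two(self):
        # This seed yields a persistent four-cell oscillation, so the
        # horizon is kept to a handful of epochs: over long oscillatory
        # runs the two integrators' rounding differences compound.
        cfg = SimulationConfig(grid=GridSpec(2, 2, "bounded"),
                               rule=LogicRule(dist=1, theta=1),
                               seed=9, t_max=12.0, **TIGHT)
        y0 = initialize(cfg)
        # bounded 2x2 adjacency: diagonal (0,0)-(1,1) pair is at distance 2
        neighbors = [[1, 2], [0, 2, 3], [0, 1, 3], [1, 2]]
        self.assert_agrees(cfg, y0, neighbors, 12.0)

    def test_symmetric_pair_crosses_simultaneously(self):
        """Two identical coupled cells preserve exchange symmetry: their
        crossings are committed together in one epoch."""
        cfg = SimulationConfig(grid=GridSpec(1, 2, "bounded"),
                               rule=LogicRule(dist=1, theta=1),
                               init_ranges={s: (0.0, 0.0)
                                            for s in hx.SPECIES},
                               t_max=5.0)
        res = run(cfg)
        first_epoch_t = res.events[0].time
        simultaneous = [e for e in res.events if e.time == first_epoch_t]
        assert len(simultaneous) == 2
        assert {e.cell for e in simultaneous} == set(cfg.grid.cells())


class TestRunContracts:
    def test_determinism_same_seed_same_events(self):
        cfg = SimulationConfig(grid=GridSpec(5, 5, "cylindrical"), seed=3,
                               t_max=60.0)
        r1, r2 = run(cfg), run(cfg)
        assert [(e.time, e.cell, e.direction) for e in r1.events] == \
               [(e.time, e.cell, e.direction) for e in r2.events]
        np.testing.assert_array_equal(r1.final_logic, r2.final_logic)

    def test_events_strictly_ordered_and_consistent(self):
        cfg = SimulationConfig(grid=GridSpec(5, 5, "cylindrical"), seed=4,
                               t_max=60.0)
        res = run(cfg)
        times = [e.time for e in res.events]
        assert all(t2 >= t1 for t1, t2 in zip(times, times[1:]))
        for e in res.events:
            assert (e.direction == "up") == (e.new_logic_value == 1)

    def test_logic_history_matches_binarized_delta(self):
        """Away from the hysteresis band the recorded logic matrix always
        equals the binarization of the recorded Delta field."""
        cfg = SimulationConfig(grid=GridSpec(5, 5, "cylindrical"), seed=6,
                               t_max=60.0)
        res = run(cfg)
        p = cfg.params
        for k in range(res.times.size):
            delta = res.states[k, :, DELTA_INDEX].reshape(5, 5)
            off_band = np.abs(delta - p.Th) > 1e-5 * p.Th
            np.testing.assert_array_equal(
                res.logic_history[k][off_band],
                binarize(delta, p.Th)[off_band])

    def test_final_logic_is_binarized_final_delta(self):
        cfg = SimulationConfig(grid=GridSpec(4, 4, "cylindrical"), seed=2,
                               t_max=80.0)
        res = run(cfg)
        np.testing.assert_array_equal(
            res.final_logic, binarize(res.final_delta, cfg.params.Th))

    def test_snapshot_times_recorded(self):
        cfg = SimulationConfig(grid=GridSpec(3, 3, "cylindrical"), seed=1,
                               t_max=30.0, snapshot_times=(5.0, 10.0))
        res = run(cfg)
        assert 5.0 in res.snapshots and 10.0 in res.snapshots
        assert res.snapshots[5.0].shape == (3, 3)

    def test_stiff_solver_path(self):
        """BDF with the block-diagonal sparsity pattern reproduces the
        default solver's terminal pattern."""
        kw = dict(grid=GridSpec(3, 3, "cylindrical"), seed=8, t_max=60.0)
        r_rk = run(SimulationConfig(**kw))
        r_bdf = run(SimulationConfig(method="BDF", **kw))
        np.testing.assert_array_equal(r_rk.final_logic, r_bdf.final_logic)
        assert len(r_rk.events) == len(r_bdf.events)
        for e1, e2 in zip(r_rk.events, r_bdf.events):
            assert e1.time == pytest.approx(e2.time, rel=1e-4)
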