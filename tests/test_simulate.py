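"""Engine correctness: SSA exactness, ODE accuracy, trace persistence."""

import numpy as np
import pytest

from hmgb1smc.fixtures import make_toy_network
from hmgb1smc.simulate import (
    SimulationConfig,
    Trace,
    TraceParseError,
    read_trace,
    simulate_ode,
    simulate_ssa,
    write_trace,
)


class TestSSA:
    def test_requires_seed_and_integer_counts(self, decay_network):
        with pytest.raises(ValueError, match="seed"):
            simulate_ssa(decay_network, SimulationConfig(t_end=1.0))
        frac = make_toy_network("decay", A0=10.5)
        with pytest.raises(ValueError, match="integer"):
            simulate_ssa(frac, SimulationConfig(t_end=1.0, seed=1))

    def test_same_seed_identical_trace(self, hmgb1_network):
        config = SimulationConfig(t_end=5.0, seed=7)
        a = simulate_ssa(hmgb1_network, config)
        b = simulate_ssa(hmgb1_network, config)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a._events[1], b._events[1])
        c = simulate_ssa(hmgb1_network, SimulationConfig(t_end=5.0, seed=8))
        assert not np.array_equal(a.times, c.times)

    def test_absorbing_state_single_sojourn(self):
        net = make_toy_network("decay", d=0.5, A0=3)
        trace = simulate_ssa(net, SimulationConfig(t_end=1000.0, seed=4))
        assert trace.series("A")[-1] == 0  # all molecules decayed
        assert trace.horizon == 1000.0
        assert trace.sojourns()[-1] > 0  # final state's sojourn extends to t_end

    def test_decay_ensemble_mean_matches_analytic(self, decay_network):
        # E[A(100)] = 1000 * exp(-0.01*100) = 367.88
        finals = []
        for seed in range(1000):
            tr = simulate_ssa(decay_network, SimulationConfig(t_end=100.0, seed=seed))
            finals.append(tr.series("A")[-1])
        mean = np.mean(finals)
        se = np.std(finals, ddof=1) / np.sqrt(len(finals))
        assert abs(mean - 1000 * np.exp(-1.0)) < 3 * se

    def test_event_steps_follow_stoichiometry(self):
        net = make_toy_network("birth_death", k=20, d=0.05)
        tr = simulate_ssa(net, SimulationConfig(t_end=30.0, seed=11))
        a = tr.series("A")
        steps = np.diff(a)
        assert set(np.unique(steps)) <= {-1.0, 1.0}
        assert a.min() >= 0

    def test_conservation_exact_on_signaling_network(self, hmgb1_network):
        tr = simulate_ssa(hmgb1_network, SimulationConfig(t_end=20.0, seed=3))
        for rel in hmgb1_network.conservation:
            total = sum(tr.series(m) for m in rel.members)
            assert np.all(total == rel.total)


class TestODE:
    def test_decay_closed_form(self, decay_network):
        tr = simulate_ode(decay_network, SimulationConfig(t_end=100.0))
        assert tr.series("A")[-1] == pytest.approx(1000 * np.exp(-1.0), rel=1e-4)

    def test_grid_and_sojourns(self, decay_network):
        tr = simulate_ode(decay_network, SimulationConfig(t_end=10.0, ode_grid_dt=0.5))
        assert len(tr) == 21
        assert np.allclose(tr.sojourns()[:-1], 0.5)

    def test_conservation_drift_small(self, hmgb1_network):
        tr = simulate_ode(hmgb1_network, SimulationConfig(t_end=1200.0))
        for rel in hmgb1_network.conservation:
            total = sum(tr.series(m) for m in rel.members)
            assert np.max(np.abs(total - rel.total)) / rel.total < 1e-6

    def test_solution_invariant_under_tighter_tolerances(self, birth_death_network):
        base = simulate_ode(birth_death_network, SimulationConfig(t_end=100.0))
        tight = simulate_ode(
            birth_death_network,
            SimulationConfig(t_end=100.0, ode_grid_dt=0.5, rtol=5e-7, atol=5e-4),
        )
        a, b = base.series("A"), tight.series("A")[::2]
        scale = max(1.0, np.max(np.abs(a)))
        assert np.max(np.abs(a - b)) / scale < 1e-4

    def test_no_negative_counts(self, hmgb1_network):
        tr = simulate_ode(hmgb1_network, SimulationConfig(t_end=600.0))
        assert tr.values_matrix().min() >= 0.0


class TestSSAOdeAgreement:
    def test_linear_network_ensemble_mean_tracks_ode(self):
        # first-order only network: SSA ensemble mean follows the ODE exactly
        net = make_toy_network("two_state_switch", k_on=0.1, k_off=0.05, A0=200)
        ode = simulate_ode(net, SimulationConfig(t_end=50.0))
        checkpoints = np.arange(5, 55, 5)
        runs = np.empty((1000, len(checkpoints)))
        for seed in range(1000):
            tr = simulate_ssa(net, SimulationConfig(t_end=50.0, seed=3_000 + seed))
            idx = np.searchsorted(tr.times, checkpoints, side="right") - 1
            runs[seed] = tr.series("A")[idx]
        mean = runs.mean(axis=0)
        se = runs.std(axis=0, ddof=1) / np.sqrt(runs.shape[0])
        expected = ode.series("A")[np.searchsorted(ode.times, checkpoints)]
        assert np.all(np.abs(mean - expected) < 3 * np.maximum(se, 1e-9))


class TestTraceIO:
    def test_round_trip(self, birth_death_network, tmp_path):
        tr = simulate_ssa(birth_death_network, SimulationConfig(t_end=10.0, seed=2))
        path = tmp_path / "trace.tsv"
        write_trace(tr, path)
        back = read_trace(path)
        assert back == tr
        assert back.origin == "ssa" and back.seed == 2 and back.horizon == 10.0

    def test_ode_round_trip(self, decay_network, tmp_path):
        tr = simulate_ode(decay_network, SimulationConfig(t_end=5.0))
        path = tmp_path / "trace.tsv"
        write_trace(tr, path)
        assert read_trace(path) == tr

    def test_decreasing_time_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("time\tA\n0.0\t5\n2.0\t4\n1.0\t3\n")
        with pytest.raises(TraceParseError, match="non-decreasing"):
            read_trace(path)

    def test_ragged_row_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("time\tA\tB\n0.0\t5\t1\n1.0\t4\n")
        with pytest.raises(TraceParseError, match="line 3"):
            read_trace(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(TraceParseError, match="empty"):
            read_trace(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("time\tA\n0.0\tfive\n")
        with pytest.raises(TraceParseError, match="line 2"):
            read_trace(path)


class TestTraceContainer:
    def test_tot_suffix_resolution(self, hmgb1_network):
        tr = simulate_ode(hmgb1_network, SimulationConfig(t_end=5.0))
        np.testing.assert_allclose(
            tr.series("AKT_tot"), tr.series("AKT") + tr.series("AKT_p")
        )
        np.testing.assert_allclose(
            tr.series("PIP_tot"), tr.series("PIP2") + tr.series("PIP3")
        )
        with pytest.raises(KeyError):
            tr.series("NOPE_tot")

    def test_horizon_must_cover_times(self):
        with pytest.raises(ValueError, match="horizon"):
            Trace(("A",), np.array([0.0, 5.0]), values=np.zeros((2, 1)),
                  horizon=4.0, origin="test")
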