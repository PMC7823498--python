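"""Continuous semantics: Hill transfer, BooleCube, ODE integration, clamps."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brnsim import (
    ActivityState,
    ClampEntry,
    Interaction,
    LogicRule,
    PerturbationSchedule,
    RegulatoryNetwork,
    SimulationConfig,
    Trajectory,
    boolecube,
    config_from_yaml,
    config_to_yaml,
    normalized_hill,
    ode_rhs,
    simulate,
    steady_state_from_trajectory,
)
from brnsim.random_networks import GeneratorSpec, random_brn


class TestNormalizedHill:
    @pytest.mark.parametrize(
        "x,expected",
        [
            (0.0, 0.0),
            (1.0, 1.0),
            (0.5, (1 + 2**-10) / 2),  # = 0.50048828125 by closed form
        ],
    )
    def test_closed_form_values(self, x, expected):
        assert normalized_hill(x, k=0.5, h=10) == pytest.approx(expected, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            normalized_hill(1.2)
        with pytest.raises(ValueError):
            normalized_hill(-0.1)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_nondecreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert normalized_hill(lo) <= normalized_hill(hi) + 1e-15


def and_not_rule():
    return LogicRule("Y", ("x1",), ("x2",), "or_and_not")


class TestBoolecube:
    def test_vertex_and_midpoint(self):
        rule = and_not_rule()
        assert boolecube(rule, {"x1": 1.0, "x2": 0.0}) == 1.0
        assert boolecube(rule, {"x1": 0.5, "x2": 0.5}) == pytest.approx(0.25)

    def test_source_zero_everywhere(self):
        rule = LogicRule("S", (), (), "source_zero")
        assert boolecube(rule, {}) == 0.0

    def test_missing_parent_named(self):
        with pytest.raises(KeyError, match="x2"):
            boolecube(and_not_rule(), {"x1": 0.3})

    @pytest.mark.parametrize("n_parents", [1, 2, 3, 5])
    def test_custom_table_agrees_on_all_vertices(self, n_parents):
        rng = np.random.default_rng(n_parents)
        parents = tuple(f"p{i}" for i in range(n_parents))
        table = tuple(int(b) for b in rng.integers(2, size=2**n_parents))
        rule = LogicRule("Y", parents, (), "custom", table=table)
        for vertex in itertools.product((0, 1), repeat=n_parents):
            inputs = {p: float(v) for p, v in zip(parents, vertex)}
            idx = sum(v << i for i, v in enumerate(vertex))
            assert boolecube(rule, inputs) == float(table[idx])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=2))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_stays_in_unit_interval(self, xs):
        val = boolecube(and_not_rule(), {"x1": xs[0], "x2": xs[1]})
        assert -1e-12 <= val <= 1 + 1e-12


class TestOdeRhs:
    def test_equilibrium_when_drive_matches_state(self):
        # Stimulus clamped 1 -> B: at B=1 the drive f(1)=1 balances decay
        net = RegulatoryNetwork(["S", "B"], [Interaction("S", "B", "activation")])
        state = ActivityState({"S": 1.0, "B": 1.0})
        sched = PerturbationSchedule(
            [ClampEntry("S", 0, 400, "clamp_constant", value=1.0)]
        )
        rates = ode_rhs(state, net, SimulationConfig(), t=0.0, schedule=sched)
        assert rates["B"] == pytest.approx(0.0, abs=1e-12)
        assert rates["S"] == 0.0  # clamped

    def test_source_node_pure_decay(self):
        net = RegulatoryNetwork(["S"], [])
        rates = ode_rhs(ActivityState({"S": 1.0}), net, SimulationConfig())
        assert rates["S"] == pytest.approx(-1.0)

    def test_half_activation_composition(self):
        # parent at the threshold drives the child at f(0.5) ~ 0.5005
        net = RegulatoryNetwork(["IP3R", "Ca2+"],
                                [Interaction("IP3R", "Ca2+", "activation")])
        rates = ode_rhs(ActivityState({"IP3R": 0.5, "Ca2+": 0.0}),
                        net, SimulationConfig())
        assert rates["Ca2+"] == pytest.approx((1 + 2**-10) / 2, abs=1e-12)


class TestSimulate:
    def test_clamped_source_charges_child_like_rc_circuit(self):
        net = RegulatoryNetwork(["S", "B"], [Interaction("S", "B", "activation")])
        sched = PerturbationSchedule(
            [ClampEntry("S", 0, 30, "clamp_constant", value=1.0)]
        )
        cfg = SimulationConfig(t_end=30.0)
        traj = simulate(net, ActivityState({"S": 1.0, "B": 0.0}), cfg, sched)
        # dx/dt = 1 - x  =>  B(t) = 1 - exp(-t); RK4 at dt=0.05 is ~1e-9 accurate
        expected = 1 - np.exp(-traj.times)
        assert np.max(np.abs(traj.series("B") - expected)) < 1e-6
        assert abs(traj.series("B")[-1] - 1.0) < 1e-3

    def test_all_zero_state_is_invariant(self):
        net = random_brn(GeneratorSpec(n_nodes=10, seed=5, inhibition_fraction=0.0))
        traj = simulate(net, ActivityState.zeros(net), SimulationConfig(t_end=5.0))
        assert np.all(traj.activities == 0.0)

    def test_first_row_has_clamps_applied(self):
        net = RegulatoryNetwork(["S", "B"], [Interaction("S", "B", "activation")])
        sched = PerturbationSchedule(
            [ClampEntry("S", 0, 10, "clamp_constant", value=0.7)]
        )
        traj = simulate(net, ActivityState({"S": 0.0, "B": 0.0}),
                        SimulationConfig(t_end=10.0), sched)
        assert traj.activities[0, 0] == 0.7

    def test_node_decays_after_clamp_window_ends(self):
        # a clamp covering only t=0 lets the node relax 1.0 -> 0 afterwards
        net = RegulatoryNetwork(["Inh"], [])
        sched = PerturbationSchedule(
            [ClampEntry("Inh", 0, 0, "clamp_constant", value=1.0)]
        )
        traj = simulate(net, ActivityState({"Inh": 1.0}),
                        SimulationConfig(t_end=20.0), sched)
        assert traj.series("Inh")[0] == 1.0
        assert traj.series("Inh")[-1] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_boundedness_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        net = random_brn(GeneratorSpec(n_nodes=12, seed=seed, acyclic=False,
                                       inhibition_fraction=0.4))
        init = ActivityState.from_vector(net, rng.random(net.n_nodes))
        for integrator in ("rk4", "euler"):
            traj = simulate(net, init,
                            SimulationConfig(t_end=5.0, integrator=integrator))
            assert np.all(traj.activities >= 0.0)
            assert np.all(traj.activities <= 1.0)

    def test_euler_and_rk4_agree_on_smooth_problem(self):
        net = RegulatoryNetwork(["S", "B"], [Interaction("S", "B", "activation")])
        sched = PerturbationSchedule(
            [ClampEntry("S", 0, 10, "clamp_constant", value=1.0)]
        )
        init = ActivityState({"S": 1.0, "B": 0.0})
        t1 = simulate(net, init, SimulationConfig(t_end=10.0), sched)
        t2 = simulate(net, init,
                      SimulationConfig(t_end=10.0, integrator="euler"), sched)
        assert np.max(np.abs(t1.activities - t2.activities)) < 0.02


class TestSteadyState:
    def test_constant_trajectory_settles(self):
        net = RegulatoryNetwork(["S"], [])
        traj = simulate(net, ActivityState({"S": 0.0}), SimulationConfig(t_end=100.0))
        finals, settled = steady_state_from_trajectory(traj, window=50.0)
        assert settled and finals.values["S"] == 0.0

    def test_pure_decay_settles_near_zero(self):
        net = RegulatoryNetwork(["S"], [])
        traj = simulate(net, ActivityState({"S": 1.0}), SimulationConfig(t_end=400.0))
        finals, settled = steady_state_from_trajectory(traj, window=50.0)
        assert settled and finals.values["S"] == pytest.approx(0.0, abs=1e-9)

    def test_oscillating_clamp_does_not_settle(self):
        net = RegulatoryNetwork(["S"], [])
        sched = PerturbationSchedule(
            [ClampEntry("S", 0, 100, "clamp_waveform",
                        baseline=0.5, amplitude=0.3, period=20.0)]
        )
        traj = simulate(net, ActivityState({"S": 0.5}),
                        SimulationConfig(t_end=100.0), sched)
        _, settled = steady_state_from_trajectory(traj, window=50.0)
        assert not settled

    def test_window_larger_than_horizon_rejected(self):
        net = RegulatoryNetwork(["S"], [])
        traj = simulate(net, ActivityState({"S": 0.0}), SimulationConfig(t_end=10.0))
        with pytest.raises(ValueError):
            steady_state_from_trajectory(traj, window=50.0)


class TestEventTimes:
    def test_first_crossing_linear_interpolation(self):
        traj = Trajectory(
            times=np.array([0.0, 1.0, 2.0]),
            activities=np.array([[0.0], [0.4], [0.8]]),
            nodes=["A"],
            config=SimulationConfig(dt=1.0, t_end=2.0),
            schedule=PerturbationSchedule(),
        )
        # crosses 0.5 a quarter of the way through [1, 2]
        assert traj.first_crossing("A") == pytest.approx(1.25)

    def test_no_crossing_returns_none(self):
        traj = Trajectory(
            times=np.array([0.0, 1.0]),
            activities=np.array([[0.1], [0.2]]),
            nodes=["A"],
            config=SimulationConfig(dt=1.0, t_end=1.0),
            schedule=PerturbationSchedule(),
        )
        assert traj.first_crossing("A") is None


class TestConfigAndExport:
    def test_config_yaml_round_trip(self):
        cfg = SimulationConfig(steepness=12, decay=0.5, threshold=0.4,
                               dt=0.1, t_end=20.0, integrator="euler",
                               edge_thresholds={("A", "B"): 0.3})
        sched = PerturbationSchedule(
            [ClampEntry("A", 0, 20, "clamp_waveform",
                        baseline=0.4, amplitude=0.2, period=10.0, phase=0.5)]
        )
        cfg2, sched2 = config_from_yaml(config_to_yaml(cfg, sched))
        assert cfg2 == cfg
        assert sched2 == sched

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(steepness=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(threshold=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(dt=-0.05)

    def test_trajectory_csv_round_trip(self, tmp_path):
        net = RegulatoryNetwork(["S", "B"], [Interaction("S", "B", "activation")])
        sched = PerturbationSchedule(
            [ClampEntry("S", 0, 5, "clamp_constant", value=1.0)]
        )
        traj = simulate(net, ActivityState({"S": 1.0, "B": 0.0}),
                        SimulationConfig(t_end=5.0), sched)
        p = tmp_path / "traj.csv"
        traj.to_csv(p)
        again = Trajectory.from_csv(p)
        assert again.nodes == traj.nodes
        assert np.allclose(again.activities, traj.activities)
        assert p.read_text().splitlines()[0] == "time_s,S,B"
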