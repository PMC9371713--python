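"""Hill kinetics, circuit compilation, integration and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypermotifs.dynamics import (
    CircuitModel,
    SignedEdge,
    Trajectory,
    build_model,
    classify_dynamics,
    find_fixed_points,
    hill,
    named_circuit,
    parse_circuit_spec,
    simulate,
    synchronization_metrics,
)


class TestHill:
    def test_half_effect(self):
        for k in (0.1, 0.5, 2.0):
            for n in (1, 2, 4):
                assert hill(k, k, n, "+") == pytest.approx(0.5)

    def test_limits(self):
        assert hill(0.0, 0.5, 2, "+") == 0.0
        assert hill(0.0, 0.5, 2, "-") == 1.0

    @given(
        x=st.floats(0, 100, allow_nan=False),
        k=st.floats(0.01, 10),
        n=st.floats(1, 6),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_complementarity(self, x, k, n):
        assert hill(x, k, n, "+") + hill(x, k, n, "-") == pytest.approx(1.0)

    def test_monotone(self):
        xs = np.linspace(0, 5, 50)
        up = [hill(x, 0.5, 2, "+") for x in xs]
        down = [hill(x, 0.5, 2, "-") for x in xs]
        assert all(np.diff(up) > 0)
        assert all(np.diff(down) < 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hill(-0.1, 0.5, 2)
        with pytest.raises(ValueError):
            hill(1.0, 0.0, 2)
        with pytest.raises(ValueError):
            hill(1.0, 0.5, 0.5)


class TestBuildModel:
    def test_self_loop_single_variable(self):
        m = named_circuit("SL")
        assert m.variables == ("X",)

    def test_c1ffl_structure(self):
        m = named_circuit("C1FFL")
        assert len(m.nodes) == 3
        assert all(e.sign == "+" for e in m.edges)
        assert m.gate_of("Z") == "AND"
        assert "X" in m.external_inputs

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="unknown node"):
            CircuitModel(nodes=("X",), edges=(SignedEdge("X", "Y", "+"),))
        with pytest.raises(ValueError):
            SignedEdge("X", "Y", "+", k=-1)
        with pytest.raises(ValueError, match="positive"):
            build_model({"nodes": ["X"], "edges": [], "beta": {"X": 0}})

    def test_spec_text_round_trip(self):
        text = """
        # toggle switch
        nodes X Y
        edge X Y - 0.5 2
        edge Y X - 0.5 2
        param X beta 2.0
        param Y beta 2.0
        """
        m = parse_circuit_spec(text)
        assert m.beta_of("X") == 2.0
        assert {(e.source, e.target, e.sign) for e in m.edges} == {
            ("X", "Y", "-"),
            ("Y", "X", "-"),
        }


class TestSimulate:
    def test_pure_decay_closed_form(self):
        m = build_model({"nodes": ["X"], "edges": []})
        traj = simulate(m, {"X": 1.0}, 5.0)
        assert traj.series("X") == pytest.approx(np.exp(-traj.t), abs=1e-6)

    def test_nonnegative_states(self):
        m = named_circuit("TMFL")
        traj = simulate(m, {"X": 1.0, "Y": 0.01}, 50.0)
        assert (traj.y >= 0).all()

    def test_rejects_negative_initial_state(self):
        m = named_circuit("SL")
        with pytest.raises(ValueError):
            simulate(m, [-0.1], 1.0)


class TestFixedPoints:
    def test_sl_bistability(self):
        fps = find_fixed_points(named_circuit("SL"))
        stable = [fp for fp in fps if fp.stable]
        assert len(stable) == 2  # OFF and ON
        assert min(fp.state[0] for fp in stable) == pytest.approx(0.0, abs=1e-6)

    def test_tmfl_switch(self):
        fps = find_fixed_points(named_circuit("TMFL"))
        assert sum(fp.stable for fp in fps) == 2
        assert sum(fp.classification == "saddle" for fp in fps) == 1

    def test_omfl_spiral(self):
        fps = find_fixed_points(named_circuit("OMFL"))
        assert len(fps) == 1
        assert fps[0].classification == "stable-spiral"


class TestClassifyDynamics:
    def _traj(self, t, x):
        return Trajectory(t=t, y=np.asarray(x)[None, :], variables=("v",))

    def test_exponential_decay_is_monotone(self):
        t = np.linspace(0, 10, 500)
        assert classify_dynamics(self._traj(t, np.exp(-t)), "v") == "monotone-converge"

    def test_single_transient_peak_is_pulse(self):
        t = np.linspace(0, 10, 500)
        x = t * np.exp(-2 * t)
        assert classify_dynamics(self._traj(t, x), "v") == "pulse"

    def test_sine_is_sustained(self):
        t = np.linspace(0, 50, 2000)
        x = 1 + 0.5 * np.sin(2 * np.pi * t / 5)
        assert classify_dynamics(self._traj(t, x), "v") == "sustained-oscillation"

    def test_decaying_sine_is_damped(self):
        t = np.linspace(0, 50, 2000)
        x = 1 + np.exp(-t / 10) * np.sin(2 * np.pi * t / 5)
        assert classify_dynamics(self._traj(t, x), "v") == "damped-oscillation"

    def test_short_trajectory_inconclusive(self):
        t = np.linspace(0, 1, 5)
        assert classify_dynamics(self._traj(t, t), "v") == "inconclusive"


class TestSynchronization:
    def _two(self, t, a, b):
        return Trajectory(t=t, y=np.vstack([a, b]), variables=("a", "b"))

    def test_identical_sinusoids_in_phase(self):
        t = np.linspace(0, 50, 4000)
        x = 1 + 0.5 * np.sin(2 * np.pi * t / 5)
        rel, lag = synchronization_metrics(self._two(t, x, x.copy()), "a", "b")
        assert rel == "in-phase"
        assert abs(lag) < 0.25

    def test_half_period_offset_anti_phase(self):
        t = np.linspace(0, 50, 4000)
        a = 1 + 0.5 * np.sin(2 * np.pi * t / 5)
        b = 1 + 0.5 * np.sin(2 * np.pi * (t - 2.5) / 5)
        rel, _ = synchronization_metrics(self._two(t, a, b), "a", "b")
        assert rel == "anti-phase"

    def test_non_oscillatory_input_gives_none(self):
        t = np.linspace(0, 50, 2000)
        rel, lag = synchronization_metrics(
            self._two(t, np.exp(-t), 1 + 0.5 * np.sin(t)), "a", "b"
        )
        assert rel == "none" and lag is None


class TestRegimes:
    """Fixture circuits land in their documented dynamical regimes (the
    full panel-by-panel matrix lives in the acceptance suite)."""

    def test_i1ffl_pulse(self):
        traj = simulate(named_circuit("I1FFL"), {"Y": 0.0, "Z": 0.0}, 30.0)
        assert classify_dynamics(traj, "Z") == "pulse"

    def test_omfl_damped_oscillation(self):
        traj = simulate(named_circuit("OMFL"), {"X": 0.0, "Y": 1.5}, 60.0)
        assert classify_dynamics(traj, "X") == "damped-oscillation"

    def test_ffl_jacobian_is_triangular_with_negative_diagonal(self):
        jac = np.array([[-1, 0, 0], [1, -1, 0], [1, 1, -1]], dtype=float)
        eig = np.linalg.eigvals(jac)
        assert eig == pytest.approx(np.full(3, -1.0))
        assert not np.iscomplex(eig).any()
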