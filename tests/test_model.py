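"""Core model tests: input signal, vector field, simulation, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapkqb.model import (Condition, DegenerateNormalizationError, ParamVec,
                          Trajectory, input_signal, normalize, rhs,
                          rhs_at_input, simulate)

from conftest import search_box_draws
from oracles import rhs_terms, rk4_fixed


class TestInputSignal:
    @pytest.mark.parametrize("t, K, expected", [
        (-1.0, 10.0, 0.0),       # before stimulation
        (0.0, 10.0, 1.0),        # jump at stimulation
        (10.0, 10.0, 0.5),       # half-decay at t = K
        (7.3, 7.3, 0.5),
    ])
    def test_closed_form_values(self, t, K, expected):
        assert input_signal(t, K) == pytest.approx(expected, abs=1e-15)

    def test_dose_scaling_and_termination(self):
        assert input_signal(3.0, 8.0, ku=2.5) == pytest.approx(
            2.5 * input_signal(3.0, 8.0))
        assert input_signal(12.0, 8.0, t_off=12.0) == 0.0
        assert input_signal(11.9, 8.0, t_off=12.0) > 0.0

    def test_rejects_bad_K(self):
        with pytest.raises(ValueError):
            input_signal(1.0, 0.0)
        with pytest.raises(ValueError):
            input_signal(1.0, -3.0)

    @given(K=st.floats(0.1, 100.0), ku=st.floats(0.0, 10.0),
           t_off=st.one_of(st.none(), st.floats(0.1, 500.0)))
    @settings(max_examples=60, deadline=None)
    def test_non_increasing_and_bounded(self, K, ku, t_off):
        t = np.linspace(0.0, 600.0, 301)
        u = input_signal(t, K, ku, t_off)
        assert np.all(np.diff(u) <= 1e-12)
        assert np.all(u >= 0.0) and np.all(u <= ku + 1e-12)


class TestRhs:
    def test_trivial_steady_state_at_origin(self):
        for th in search_box_draws(0, 5):
            for cond in (Condition.ngf_control(ku=0.0),
                         Condition.egf_control(ku=0.0)):
                d = rhs_at_input(np.zeros(4), 0.0, th, cond)
                assert np.all(d == 0.0)

    def test_feedback_gated_by_flags(self):
        th = search_box_draws(1, 1)[0]
        x = np.array([0.3, 0.4, 0.1, 0.2])
        base = Condition()  # fp = fn = False
        d0 = rhs_at_input(x, 0.7, th, base)
        d1 = rhs_at_input(x, 0.7, th.scaled("kFp", 100.0).scaled("kFn", 100.0),
                          base)
        np.testing.assert_array_equal(d0, d1)

    def test_term_by_term_oracle(self):
        """The vector field matches an independent term-by-term re-evaluation."""
        rng = np.random.default_rng(5)
        for th in search_box_draws(2, 10):
            x = rng.uniform(0.0, 0.5, 4)
            t = rng.uniform(0.0, 60.0)
            for fp, fn in ((True, False), (False, True), (False, False)):
                cond = Condition(fp=fp, fn=fn, s=(0.9, 0.8, 0.7))
                u = input_signal(t, th.K)
                expected = rhs_terms(x, u, th.to_dict(), fp, fn,
                                     s=(0.9, 0.8, 0.7))
                np.testing.assert_allclose(rhs(x, t, th, cond), expected,
                                           rtol=1e-12, atol=1e-15)

    def test_intervention_switches(self):
        th = search_box_draws(3, 1)[0]
        x = np.array([0.2, 0.1, 0.05, 0.1])
        mek = rhs_at_input(x, 1.0, th, Condition.ngf_control(mek_inhibited=True))
        expected = rhs_terms(x, 1.0, th.to_dict(), True, False,
                             mek_inhibited=True)
        np.testing.assert_allclose(mek, expected, rtol=1e-12)
        nofb = rhs_at_input(x, 1.0, th,
                            Condition.ngf_control(feedback_removed=True))
        expected = rhs_terms(x, 1.0, th.to_dict(), True, False,
                             feedback_removed=True)
        np.testing.assert_allclose(nofb, expected, rtol=1e-12)


class TestSimulate:
    def test_zero_feedback_strength_equals_no_feedback(self):
        th = search_box_draws(4, 1)[0]
        th_tiny = ParamVec.from_dict({**th.to_dict(), "kFp": 1e-300})
        t = np.array([0.0, 5.0, 15.0, 60.0])
        y_fp = simulate(th_tiny, Condition.ngf_control(), t).states
        y_off = simulate(th_tiny, Condition(), t).states
        np.testing.assert_allclose(y_fp, y_off, atol=1e-9)

    def test_mek_inhibition_zeroes_downstream(self):
        th = search_box_draws(5, 1)[0]
        t = np.linspace(0.0, 60.0, 61)
        y = simulate(th, Condition.ngf_control(mek_inhibited=True), t).states
        assert np.all(np.abs(y[:, 1:]) < 1e-12)
        assert y[:, 0].max() > 0.0  # pRaf still responds to the input

    @pytest.mark.parametrize("method", ["rk45", "lsoda"])
    def test_agrees_with_fixed_step_rk4_oracle(self, method):
        """Adaptive solvers match a fixed-step RK4 reference at h = 1e-3 min."""
        t_grid = np.array([0.0, 2.0, 5.0, 10.0, 20.0, 30.0])
        for i, th in enumerate(search_box_draws(6, 7)):
            cond = Condition.ngf_control() if i % 2 else Condition.egf_control()
            y = simulate(th, cond, t_grid, method=method).states

            def f(x, t, _th=th, _c=cond):
                return rhs(x, t, _th, _c)

            ref = rk4_fixed(f, np.zeros(4), t_grid, h=1e-3)
            scale = np.abs(ref).max()
            assert np.max(np.abs(y - ref)) / scale < 1e-4

    def test_rk45_matches_lsoda(self):
        t_grid = np.linspace(0.0, 600.0, 121)
        for th in search_box_draws(7, 5):
            a = simulate(th, Condition.ngf_control(), t_grid, method="rk45").states
            b = simulate(th, Condition.ngf_control(), t_grid, method="lsoda").states
            assert np.max(np.abs(a - b)) < 1e-5

    def test_conservation_bounds(self):
        s = (0.72, 0.7, 0.65)
        t = np.linspace(0.0, 120.0, 241)
        for th in search_box_draws(8, 10):
            y = simulate(th, Condition.ngf_control(s=s), t).states
            assert np.all(y >= -1e-8)
            assert np.all(y[:, 0] <= s[0] + 1e-8)
            assert np.all(y[:, 1] <= s[1] + 1e-8)
            assert np.all(y[:, 2] + y[:, 3] <= s[2] + 1e-8)

    def test_origin_globally_attracting_without_positive_feedback(self):
        """With no input and no positive feedback every state decays to rest."""
        rng = np.random.default_rng(11)
        t = np.array([0.0, 2500.0, 5000.0])
        for th in search_box_draws(9, 5):
            x0 = rng.uniform(0.0, 0.4, 4)
            cond = Condition.egf_control(ku=0.0)
            y = simulate(th, cond, t, x0=x0).states
            assert np.linalg.norm(y[-1]) < 1e-6

    def test_signal_termination_freezes_input(self):
        th = search_box_draws(10, 1)[0]
        t = np.array([0.0, 1.0, 2.0, 3.0, 10.0, 30.0])
        y_off = simulate(th, Condition.egf_control(t_off=2.0), t).states
        y_on = simulate(th, Condition.egf_control(), t).states
        np.testing.assert_allclose(y_off[:3], y_on[:3], atol=1e-9)
        assert y_off[-1, 3] <= y_on[-1, 3] + 1e-12

    def test_feedback_removal_consistent_across_methods(self, theta_B):
        t = np.array([0.0, 5.0, 30.0, 60.0])
        cond = Condition.ngf_control(feedback_removed=True)
        a = simulate(theta_B, cond, t, method="rk45").states
        b = simulate(theta_B, cond, t, method="lsoda").states
        np.testing.assert_allclose(a, b, atol=1e-6)
        ctrl = simulate(theta_B, Condition.ngf_control(), t, method="rk45").states
        assert not np.allclose(a, ctrl)

    def test_deterministic(self):
        th = search_box_draws(12, 1)[0]
        t = np.linspace(0.0, 60.0, 20)
        a = simulate(th, Condition.ngf_control(), t).states
        b = simulate(th, Condition.ngf_control(), t).states
        np.testing.assert_array_equal(a, b)


class TestNormalize:
    def _traj(self, states, times=None):
        th = search_box_draws(13, 1)[0]
        times = np.arange(len(states), dtype=float) if times is None else times
        return Trajectory(times=times, states=np.asarray(states, dtype=float),
                          condition=Condition.ngf_control(), theta=th)

    def test_reference_anchors_to_one_and_scale_invariance(self):
        th = search_box_draws(14, 1)[0]
        t = np.array([0.0, 2.0, 5.0, 30.0, 60.0])
        traj = simulate(th, Condition.ngf_control(), t)
        z = normalize(traj, 5.0)
        np.testing.assert_allclose(z[2], 1.0, atol=1e-12)
        doubled = Trajectory(times=t, states=2.0 * traj.states,
                             condition=traj.condition, theta=th)
        np.testing.assert_allclose(normalize(doubled, 5.0), z, rtol=1e-12)

    def test_constant_trajectory_normalizes_to_one(self):
        states = np.tile([0.3, 0.2, 0.1, 0.4], (6, 1))
        z = normalize(self._traj(states), t_ref=2.0)
        np.testing.assert_allclose(z, 1.0)

    def test_zero_reference_raises(self):
        states = np.zeros((6, 4))
        with pytest.raises(DegenerateNormalizationError):
            normalize(self._traj(states), t_ref=2.0)


class TestParamVecAndExport:
    def test_serialization_round_trip(self):
        th = search_box_draws(15, 1)[0]
        assert ParamVec.from_json(th.to_json()) == th
        np.testing.assert_array_equal(ParamVec.from_array(th.to_array()).to_array(),
                                      th.to_array())

    def test_validation(self):
        good = search_box_draws(16, 1)[0].to_dict()
        with pytest.raises(ValueError):
            ParamVec.from_dict({**good, "k1p": -1.0})
        with pytest.raises(ValueError):
            ParamVec.from_dict({**good, "g": 0.5})
        with pytest.raises(ValueError):
            Condition(fp=True, fn=True)

    def test_trajectory_frame_schema(self):
        th = search_box_draws(17, 1)[0]
        t = np.array([0.0, 5.0, 60.0])
        df = simulate(th, Condition.ngf_control(), t).to_frame("ngf")
        assert list(df.columns) == ["condition_id", "time_min", "species",
                                    "value", "normalized_value"]
        assert set(df["species"]) == {"pRaf", "ppMEK", "pERK", "ppERK"}
        anchor = df[(df["time_min"] == 5.0) & (df["species"] == "ppERK")]
        assert anchor["normalized_value"].iloc[0] == pytest.approx(1.0)
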