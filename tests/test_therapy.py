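"""Radiation kill, fraction events, and the piecewise course simulator."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tricomp import (
    GrowthParams,
    LQParams,
    Schedule,
    T_FLOOR,
    TransitionParams,
    TumorState,
    apply_fraction,
    finite_duration_fraction,
    lq_survival,
    run_course,
    simulate_growth,
    three_comp_rhs,
    treated_rhs,
)

from conftest import TABLE_RATES, oracle_rhs, rk4_integrate

FIG3_LQ = LQParams(alpha1=0.35, beta1=0.035, alpha2=0.231, beta2=0.035)
FROZEN = GrowthParams(a=0.0, b=0.0)
NO_TRANSITIONS = TransitionParams.zero()


class TestLQSurvival:
    def test_zero_dose_full_survival(self):
        assert lq_survival(0.0, 0.35, 0.035) == 1.0

    def test_pure_exponential_limit(self):
        assert lq_survival(2.5, 0.4, 0.0) == pytest.approx(math.exp(-1.0))

    def test_reference_value(self):
        # high-precision exp(-(0.35*3 + 0.035*9))
        assert lq_survival(3.0, 0.35, 0.035) == pytest.approx(
            0.2553806759880777, rel=1e-14
        )

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError, match="dose"):
            lq_survival(-1.0, 0.35, 0.035)

    @given(
        d=st.floats(0.0, 20.0),
        alpha=st.floats(0.0, 1.0),
        beta=st.floats(0.0, 0.2),
    )
    def test_bounds(self, d, alpha, beta):
        s = lq_survival(d, alpha, beta)
        assert 0.0 < s <= 1.0


class TestLQParams:
    def test_ratios(self):
        assert FIG3_LQ.alpha_beta_1 == pytest.approx(10.0)
        assert FIG3_LQ.alpha_beta_2 == pytest.approx(6.6)
        assert LQParams(0.3, 0.0, 0.2, 0.035).alpha_beta_1 is None

    def test_from_ratios(self):
        lq = LQParams.from_ratios(10.0, 6.6)
        assert lq.alpha1 == pytest.approx(0.35)
        assert lq.alpha2 == pytest.approx(0.231)
        with pytest.raises(ValueError, match="beta"):
            LQParams.from_ratios(10.0, 6.6, beta1=0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="alpha2"):
            LQParams(0.3, 0.03, -0.2, 0.03)


class TestTreatedRHS:
    def test_zero_dose_reduces_to_untreated(self, breast_3c):
        g, tr = breast_3c
        s = TumorState(0, 100.0, 40.0, 10.0)
        assert treated_rhs(s, g, tr, FIG3_LQ, D=0.0) == pytest.approx(
            three_comp_rhs(s, g, tr)
        )

    def test_zero_sensitivity_reduces_to_untreated(self, breast_3c):
        g, tr = breast_3c
        s = TumorState(0, 100.0, 40.0, 10.0)
        assert treated_rhs(s, g, tr, LQParams.zero(), D=2.0) == pytest.approx(
            three_comp_rhs(s, g, tr)
        )

    def test_kill_terms_read_off_the_rate_form(self, breast_3c):
        g, tr = breast_3c
        s = TumorState(0, 100.0, 40.0, 10.0)
        D = 2.0
        base = three_comp_rhs(s, g, tr)
        treated = treated_rhs(s, g, tr, FIG3_LQ, D=D)
        kill = sum(treated) - sum(base)
        expected = -(
            (FIG3_LQ.alpha1 * D + 2 * FIG3_LQ.beta1 * D**2) * s.T_A
            + (FIG3_LQ.alpha2 * D + 2 * FIG3_LQ.beta2 * D**2) * s.T_Q
        )
        assert kill == pytest.approx(expected, rel=1e-12)

    def test_kill_to_td_conserves_volume(self, breast_3c):
        g, tr = breast_3c
        s = TumorState(0, 100.0, 40.0, 10.0)
        base = three_comp_rhs(s, g, tr)
        routed = treated_rhs(s, g, tr, FIG3_LQ, D=2.0, kill_to_td=True)
        assert sum(routed) == pytest.approx(sum(base), rel=1e-12)


class TestApplyFraction:
    def test_zero_dose_identity(self):
        s = TumorState(1.0, 100.0, 40.0, 10.0)
        assert apply_fraction(s, 0.0, FIG3_LQ) == s

    def test_reference_kill(self):
        s = TumorState(0, 100.0, 0.0, 0.0)
        out = apply_fraction(s, 3.0, FIG3_LQ)
        assert out.T_A == pytest.approx(25.53806759880777, rel=1e-13)
        assert out.T_Q == 0.0 and out.T_D == 0.0 and out.t == 0.0

    def test_kill_to_td_moves_killed_volume(self):
        s = TumorState(0, 100.0, 50.0, 0.0)
        out = apply_fraction(s, 3.0, FIG3_LQ, kill_to_td=True)
        assert out.total() == pytest.approx(s.total(), rel=1e-12)
        assert out.T_D > 0

    @given(d=st.floats(0.0, 10.0))
    def test_two_half_fractions_compose(self, d):
        """Consecutive equal fractions multiply survivals (exponent additivity)."""
        s = TumorState(0, 80.0, 30.0, 5.0)
        twice = apply_fraction(apply_fraction(s, d, FIG3_LQ), d, FIG3_LQ)
        per = lq_survival(d, FIG3_LQ.alpha1, FIG3_LQ.beta1)
        perq = lq_survival(d, FIG3_LQ.alpha2, FIG3_LQ.beta2)
        assert twice.T_A == pytest.approx(80.0 * per**2, rel=1e-12)
        assert twice.T_Q == pytest.approx(30.0 * perq**2, rel=1e-12)

    @given(d1=st.floats(0.0, 10.0), d2=st.floats(0.0, 10.0))
    def test_dose_monotonicity(self, d1, d2):
        """Post-fraction viable volume is non-increasing in dose."""
        lo, hi = sorted((d1, d2))
        s = TumorState(0, 80.0, 30.0, 5.0)
        assert apply_fraction(s, hi, FIG3_LQ).viable() <= apply_fraction(
            s, lo, FIG3_LQ
        ).viable() + 1e-12


class TestSchedule:
    def test_uniform(self):
        sched = Schedule.uniform(dose=3.0, n=12, gap=1.0)
        assert len(sched) == 12
        assert sched.cumulative_dose() == pytest.approx(36.0)
        assert sched.times == tuple(float(i) for i in range(12))

    def test_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            Schedule(times=(0.0, 0.0), doses=(1.0, 1.0))
        with pytest.raises(ValueError, match="doses"):
            Schedule(times=(0.0,), doses=(-1.0,))
        with pytest.raises(ValueError, match="fractions"):
            Schedule.uniform(dose=2.0, n=0)

    def test_csv_roundtrip(self, tmp_path):
        sched = Schedule.uniform(dose=2.0, n=5, gap=1.5)
        path = tmp_path / "sched.csv"
        sched.to_csv(path)
        assert Schedule.from_csv(path) == sched


class TestRunCourse:
    def test_empty_schedule_equals_untreated_growth(self, breast_3c):
        g, tr = breast_3c
        s0 = TumorState(0, 10.0, 4.0, 1.0)
        treated = run_course(
            s0, g, tr, FIG3_LQ, Schedule.empty(), t_end=20.0, dt_out=0.5
        )
        untreated = simulate_growth(s0, g, tr, t_end=20.0, dt_out=0.5)
        np.testing.assert_array_equal(treated.times, untreated.times)
        np.testing.assert_allclose(treated.states, untreated.states, rtol=1e-12)

    def test_zero_dose_fraction_is_piecewise_consistent(self, breast_3c):
        g, tr = breast_3c
        s0 = TumorState(0, 10.0, 4.0, 1.0)
        sched = Schedule(times=(5.0,), doses=(0.0,))
        treated = run_course(s0, g, tr, FIG3_LQ, sched, t_end=10.0, dt_out=0.5)
        untreated = simulate_growth(s0, g, tr, t_end=10.0, dt_out=0.5)
        # drop the duplicated zero-dose event row before comparing
        keep = np.concatenate(([True], np.diff(treated.times) > 0))
        np.testing.assert_allclose(
            treated.states[keep], untreated.states, rtol=1e-7
        )

    def test_frozen_growth_survival_algebra(self):
        """With growth off, N fractions of D give exp(-N(aD+bD^2)) exactly."""
        s0 = TumorState(0, 100.0, 60.0, 0.0)
        N, D = 5, 2.0
        traj = run_course(
            s0, FROZEN, NO_TRANSITIONS, FIG3_LQ,
            Schedule.uniform(D, N), t_end=float(N - 1), dt_out=1.0,
        )
        end = traj.final()
        sA = math.exp(-N * (FIG3_LQ.alpha1 * D + FIG3_LQ.beta1 * D**2))
        sQ = math.exp(-N * (FIG3_LQ.alpha2 * D + FIG3_LQ.beta2 * D**2))
        assert end.T_A == pytest.approx(100.0 * sA, rel=1e-12)
        assert end.T_Q == pytest.approx(60.0 * sQ, rel=1e-12)

    def test_half_courses_compose_to_full_course(self, breast_3c):
        g, tr = breast_3c
        s0 = TumorState(0, 500.0, 200.0, 0.0)
        full = run_course(
            s0, g, tr, FIG3_LQ, Schedule.uniform(3.0, 12), t_end=11.0, dt_out=0.5
        )
        first = run_course(
            s0, g, tr, FIG3_LQ, Schedule.uniform(3.0, 6), t_end=6.0, dt_out=0.5
        )
        second = run_course(
            first.final(), g, tr, FIG3_LQ, Schedule.uniform(3.0, 6),
            t_end=5.0, dt_out=0.5,
        )
        np.testing.assert_allclose(
            second.states[-1], full.states[-1], rtol=1e-7
        )

    def test_records_pre_and_post_fraction_states(self, breast_3c):
        g, tr = breast_3c
        s0 = TumorState(0, 100.0, 40.0, 0.0)
        traj = run_course(
            s0, g, tr, FIG3_LQ, Schedule.uniform(3.0, 3), t_end=2.0, dt_out=0.5
        )
        sA = lq_survival(3.0, FIG3_LQ.alpha1, FIG3_LQ.beta1)
        for t_f in (0.0, 1.0, 2.0):
            idx = np.nonzero(traj.times == t_f)[0]
            assert len(idx) == 2  # pre- and post-fraction rows
            pre, post = traj.states[idx[0]], traj.states[idx[1]]
            assert post[0] == pytest.approx(pre[0] * sA, rel=1e-12)
            assert post[2] == pytest.approx(pre[2], rel=1e-12)

    def test_final_state_matches_piecewise_rk4_oracle(self, breast_3c, rk4):
        """Course endpoint vs an independent fine-step piecewise integration."""
        g, tr = breast_3c
        s0 = TumorState(0, 500.0, 200.0, 0.0)
        n, dose = 12, 3.0
        traj = run_course(
            s0, g, tr, FIG3_LQ, Schedule.uniform(dose, n),
            t_end=float(n - 1), dt_out=1.0,
        )
        y = s0.as_array()
        sA = lq_survival(dose, FIG3_LQ.alpha1, FIG3_LQ.beta1)
        sQ = lq_survival(dose, FIG3_LQ.alpha2, FIG3_LQ.beta2)
        for i in range(n):
            y = y * np.array([sA, sQ, 1.0])
            if i < n - 1:
                y = rk4(y, 1.0, 1e-3, lambda v: oracle_rhs(v, g.a, g.b, **TABLE_RATES))
        np.testing.assert_allclose(traj.states[-1], y, rtol=1e-5)

    def test_schedule_beyond_horizon_rejected(self, breast_3c):
        g, tr = breast_3c
        with pytest.raises(ValueError, match="beyond"):
            run_course(
                TumorState(0, 10.0), g, tr, FIG3_LQ,
                Schedule.uniform(2.0, 5), t_end=3.0,
            )

    def test_end_of_course_viable_decreasing_in_dose(self, breast_3c):
        g, tr = breast_3c
        s0 = TumorState(0, 500.0, 200.0, 0.0)
        ends = []
        for dose in (1.0, 2.0, 3.0):
            traj = run_course(
                s0, g, tr, FIG3_LQ, Schedule.uniform(dose, 8), t_end=7.0, dt_out=1.0
            )
            ends.append(traj.final().viable())
        assert ends[0] > ends[1] > ends[2]

    def test_alpha_sensitivity_ordering(self, breast_3c):
        """At fixed beta, larger alpha gives a smaller end-of-course volume."""
        g, tr = breast_3c
        s0 = TumorState(0, 500.0, 200.0, 0.0)
        ends = []
        for alpha1 in (0.1, 0.25, 0.4):
            lq = LQParams(alpha1, 0.035, 0.231, 0.035)
            traj = run_course(
                s0, g, tr, lq, Schedule.uniform(2.0, 8), t_end=7.0, dt_out=1.0
            )
            ends.append(traj.final().viable())
        assert ends[0] > ends[1] > ends[2]

    def test_eradicated_state_never_regrows(self, breast_3c):
        g, tr = breast_3c
        s0 = TumorState(0, T_FLOOR / 2, T_FLOOR / 2, 0.0)
        traj = simulate_growth(s0, g, tr, t_end=30.0, dt_out=1.0)
        assert np.all(traj.viable() <= s0.viable() + 1e-15)


class TestFiniteDurationFraction:
    def test_growth_frozen_matches_instantaneous_for_any_duration(self):
        s = TumorState(0, 100.0, 60.0, 10.0)
        inst = apply_fraction(s, 3.0, FIG3_LQ)
        for duration in (0.01, 0.1, 1.0):
            out = finite_duration_fraction(
                s, 3.0, duration, FROZEN, NO_TRANSITIONS, FIG3_LQ,
                include_growth=False, rtol=1e-12, atol=1e-14,
            )
            assert out.T_A == pytest.approx(inst.T_A, rel=1e-9)
            assert out.T_Q == pytest.approx(inst.T_Q, rel=1e-9)

    def test_short_window_with_growth_converges_to_instantaneous(self, breast_3c):
        g, tr = breast_3c
        s = TumorState(0, 100.0, 60.0, 10.0)
        inst = apply_fraction(s, 3.0, FIG3_LQ)
        out = finite_duration_fraction(s, 3.0, 1e-6, g, tr, FIG3_LQ)
        assert out.T_A == pytest.approx(inst.T_A, rel=1e-6)
        assert out.T_Q == pytest.approx(inst.T_Q, rel=1e-6)

    def test_zero_dose_is_pure_growth(self, breast_3c):
        g, tr = breast_3c
        s = TumorState(0, 10.0, 4.0, 1.0)
        out = finite_duration_fraction(s, 0.0, 2.0, g, tr, FIG3_LQ)
        grown = simulate_growth(s, g, tr, t_end=2.0, dt_out=2.0).final()
        assert out.T_A == pytest.approx(grown.T_A, rel=1e-8)
        assert out.T_Q == pytest.approx(grown.T_Q, rel=1e-8)
        assert out.T_D == pytest.approx(grown.T_D, rel=1e-8)

    def test_invalid_duration_rejected(self, breast_3c):
        g, tr = breast_3c
        with pytest.raises(ValueError, match="duration"):
            finite_duration_fraction(
                TumorState(0, 1.0), 2.0, 0.0, g, tr, FIG3_LQ
            )
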