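import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reachat.errors import DegenerateStateError
from reachat.tumor_model import (
    DoseSignal,
    SubpopParams,
    TumorState,
    growth_rhs,
    logistic_closed_form,
    restore_index,
    simulate,
)
from .conftest import draw_params


def make_params(**kw) -> SubpopParams:
    base = dict(r_h=0.35, r_a=0.30, K_h=2000.0, K_a=2000.0, a=0.8, h=1.2, E_osi=1.0)
    base.update(kw)
    return SubpopParams(**base)


class TestGrowthRhs:
    def test_drug_free_sensitive_rate(self):
        p = make_params(r_h=0.2, K_h=1000.0, a=0.4)
        dH, _ = growth_rhs(TumorState(0, 500.0, 100.0), p, 0.0)
        assert dH == pytest.approx(46.0, abs=1e-12)

    def test_logistic_equilibrium(self):
        p = make_params(K_h=1000.0)
        dH, dA = growth_rhs(TumorState(0, 1000.0, 0.0), p, 0.0)
        assert dH == pytest.approx(0.0, abs=1e-12)
        assert dA == 0.0

    def test_drug_term(self):
        p = make_params(r_h=0.2, K_h=1000.0, a=0.4, E_osi=1.5)
        dH, dA = growth_rhs(TumorState(0, 500.0, 100.0), p, 1.0)
        assert dH == pytest.approx(46.0 - 1.5 * 500.0 * (500.0 / 600.0), rel=1e-12)
        dH0, dA0 = growth_rhs(TumorState(0, 500.0, 100.0), p, 0.0)
        assert dA == dA0  # resistant equation untouched by the drug

    def test_empty_tumor_drug_factor(self):
        p = make_params()
        dH, dA = growth_rhs(TumorState(0, 0.0, 0.0), p, 1.0)
        assert dH == 0.0 and dA == 0.0

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            TumorState(0, math.nan, 1.0)

    @given(
        H=st.floats(0.0, 3000.0),
        A=st.floats(0.0, 3000.0),
        c=st.floats(0.0, 2.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_resistant_rate_independent_of_dose(self, H, A, c):
        p = make_params()
        _, dA_on = growth_rhs(TumorState(0, H, A), p, c)
        _, dA_off = growth_rhs(TumorState(0, H, A), p, 0.0)
        assert dA_on == dA_off


class TestRestoreIndex:
    def test_hand_value(self):
        p = make_params(E_osi=2.0, r_a=0.1, K_a=1000.0, h=0.5)
        ri = restore_index(TumorState(0, 100.0, 50.0), p)
        # numerator 2*100*(100/150); denominator 0.1*50*(1 - 100/1000)
        assert ri == pytest.approx(133.333333 / 4.5, rel=1e-6)
        assert ri == pytest.approx(29.6296296, rel=1e-6)

    def test_zero_numerator(self):
        p = make_params(E_osi=0.0)
        assert restore_index(TumorState(0, 100.0, 50.0), p) == 0.0

    def test_infinite_at_capacity(self):
        p = make_params(h=0.0, K_a=500.0)
        assert restore_index(TumorState(0, 10.0, 500.0), p) == math.inf

    def test_degenerate_state(self):
        p = make_params(E_osi=0.0)
        with pytest.raises(DegenerateStateError):
            restore_index(TumorState(0, 100.0, 0.0), p)

    def test_strictly_decreasing_in_resistant_volume(self):
        p = make_params()
        H = 400.0
        values = [
            restore_index(TumorState(0, H, A), p)
            for A in np.linspace(10.0, 900.0, 40)
        ]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_positive_iff_drug_can_act(self):
        p = make_params()
        assert restore_index(TumorState(0, 100.0, 50.0), p) > 0
        assert restore_index(TumorState(0, 0.0, 50.0), p) == 0.0


class TestLogisticClosedForm:
    def test_hand_value(self):
        assert logistic_closed_form(0.2, 1000.0, 200.0, 10.0) == pytest.approx(648.8, abs=0.05)

    def test_identity_at_zero(self):
        assert logistic_closed_form(0.3, 1500.0, 123.0, 0.0) == pytest.approx(123.0, rel=1e-14)

    def test_asymptote(self):
        assert abs(logistic_closed_form(0.3, 1500.0, 10.0, 1e4) - 1500.0) < 1e-9 * 1500.0

    def test_absorbing_zero(self):
        assert logistic_closed_form(0.3, 1500.0, 0.0, 5.0) == 0.0


class TestSimulate:
    @pytest.mark.parametrize("which", ["H", "A"])
    def test_decoupled_limit_matches_closed_form(self, rng, params, which):
        for _ in range(5):
            p = draw_params(rng, params)
            x0 = 150.0
            init = TumorState(0, x0, 0.0) if which == "H" else TumorState(0, 0.0, x0)
            t = np.array([5.0, 10.0, 20.0, 50.0])
            traj = simulate(p, init, DoseSignal.off(), 50.0, t_eval=t)
            r, K = (p.r_h, p.K_h) if which == "H" else (p.r_a, p.K_a)
            ref = logistic_closed_form(r, K, x0, t)
            got = traj.H[1:] if which == "H" else traj.A[1:]
            assert np.max(np.abs(got - ref) / ref) < 1e-6

    def test_non_negative_under_strong_dosing(self, params):
        p = params.with_(E_osi=10.0)
        traj = simulate(p, TumorState(0, 500.0, 5.0), DoseSignal.continuous(0.0), 40.0)
        assert np.all(traj.H >= 0.0) and np.all(traj.A >= 0.0)

    def test_first_state_is_initial_state(self, params, init_mixed):
        traj = simulate(params, init_mixed, DoseSignal.off(), 10.0)
        assert traj.t[0] == 0.0
        assert traj.H[0] == init_mixed.H and traj.A[0] == init_mixed.A

    def test_untreated_mixed_growth_monotone(self, params, init_mixed):
        traj = simulate(params, init_mixed, DoseSignal.off(), 30.0,
                        t_eval=np.linspace(0, 30, 301))
        V = traj.V
        below = V < 0.99 * (params.K_h)  # before capacity effects dominate
        dV = np.diff(V)
        assert np.all(dV[below[:-1]] > 0)

    def test_matches_dense_euler(self, rng, params, init_mixed):
        dose = DoseSignal([(2.0, 4.0), (7.0, 9.0)])
        for _ in range(5):
            p = draw_params(rng, params)
            traj = simulate(p, init_mixed, dose, 10.0, t_eval=[10.0])
            # fixed-step Euler oracle, dt = 1e-4 day
            dt = 1e-4
            H, A = init_mixed.H, init_mixed.A
            t = 0.0
            while t < 10.0 - dt / 2:
                c = dose.at(t)
                dH, dA = growth_rhs(TumorState(t, H, A), p, c)
                H, A = max(H + dt * dH, 0.0), max(A + dt * dA, 0.0)
                t += dt
            V_euler = H + A
            V_solver = traj.H[-1] + traj.A[-1]
            assert abs(V_solver - V_euler) / V_euler < 1e-3

    def test_bad_horizon_rejected(self, params, init_mixed):
        with pytest.raises(ValueError):
            simulate(params, init_mixed, DoseSignal.off(), -1.0)


class TestDoseSignal:
    def test_roundtrip(self):
        d = DoseSignal([(2.0, 4.0), (10.0, math.inf)])
        assert DoseSignal.decode(d.encode()) == d
        assert DoseSignal.decode("") == DoseSignal.off()

    def test_at_and_switch_times(self):
        d = DoseSignal([(2.0, 4.0)])
        assert d.at(1.9) == 0.0 and d.at(2.0) == 1.0 and d.at(4.0) == 0.0
        assert d.switch_times(0.0, 10.0) == [2.0, 4.0]

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            DoseSignal([(0.0, 3.0), (2.0, 5.0)])
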