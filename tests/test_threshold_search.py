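import math

import numpy as np
import pandas as pd
import pytest

from reachat.errors import ConfigurationError, ExtrapolationError, InsufficientDataError
from reachat.protocols import ProtocolSpec, run_protocol
from reachat.threshold_search import (
    PlanSpec,
    default_plan_grid,
    default_ri_duration_grid,
    ri_duration_study,
    ri_response_corpus,
    ri_response_map,
    run_plan,
    screen_plans,
    select_threshold,
)
from reachat.tumor_model import TumorState, restore_index


@pytest.fixture(scope="module")
def at1_reference(params):
    init = TumorState(0.0, 180.0, 20.0)
    spec = ProtocolSpec(kind="at1")
    return init, spec, run_protocol(params, init, spec)


class TestPlans:
    def test_exactly_three_cycles_enforced(self):
        with pytest.raises(ConfigurationError):
            PlanSpec(t_first_cycle=5.0, dosing=(2.0, 2.0), withdrawal=(2.0, 2.0))
        with pytest.raises(ConfigurationError):
            PlanSpec(t_first_cycle=5.0, dosing=(1.0, 2.0, 2.0))

    def test_reference_like_plan_is_admissible(self, params, at1_reference):
        # a plan reproducing the reference schedule (2-day blocks, withdrawal
        # to the trigger, no interruption) ties the reference outcome
        init, spec, ref = at1_reference
        plan = PlanSpec(
            t_first_cycle=ref.cycles[0].t_start,
            dosing=(2.0, 2.0, 2.0),
            withdrawal=(50.0, 50.0, 50.0),  # truncated at the trigger volume
        )
        res = screen_plans(params, init, [plan], ref, spec)
        assert len(res.admissible) == 1
        assert res.admissible[0].switching_ri is None
        assert res.ri_range is None  # no interrupting plan

    def test_resistant_free_skip_plan_ties_censored_reference(self, params):
        init = TumorState(0.0, 250.0, 0.0)
        spec = ProtocolSpec(kind="at1", horizon=60.0)
        ref = run_protocol(params, init, spec)
        assert ref.censored
        plan = PlanSpec(t_first_cycle=ref.cycles[0].t_start, skip_withdrawal_from=1)
        res = screen_plans(params, init, [plan], ref, spec)
        # continuous dosing on a pure-sensitive tumor never progresses either
        assert len(res.admissible) == 1
        assert res.switching_values == ()  # switching index is infinite there

    def test_empty_plan_grid_rejected(self, params, at1_reference):
        init, spec, ref = at1_reference
        with pytest.raises(ConfigurationError):
            screen_plans(params, init, [], ref, spec)

    def test_default_screen_closure(self, params, at1_reference):
        init, spec, ref = at1_reference
        plans = default_plan_grid(ref.cycles[0].t_start)
        res = screen_plans(params, init, plans, ref, spec)
        assert res.ri_range is not None
        lo, hi = res.ri_range
        assert lo <= hi and len(res.switching_values) > 0
        assert all(v > 0 for v in res.switching_values)
        assert lo == math.floor(min(res.switching_values))
        assert hi == math.ceil(max(res.switching_values))

    def test_switching_ri_consistent_with_trajectory(self, params, at1_reference):
        init, spec, ref = at1_reference
        plans = default_plan_grid(ref.cycles[0].t_start)
        res = screen_plans(params, init, plans, ref, spec)
        checked = 0
        for out in res.admissible:
            if out.switching_ri is None or not math.isfinite(out.switching_ri):
                continue
            traj = out.trajectory
            i = int(np.argmin(np.abs(traj.t - out.switch_time)))
            ri = restore_index(traj.state_at(i), params)
            assert ri == pytest.approx(out.switching_ri, abs=1e-9)
            checked += 1
        assert checked > 0


class TestSelect:
    def test_singleton_range(self, params, init_mixed):
        grid = {"r_a": [1.0, 1.4], "a": [0.5, 1.5]}
        with pytest.warns(UserWarning):
            res = select_threshold((7, 7), grid, params, init_mixed)
        assert res.threshold == 7

    def test_threshold_zero_reproduces_classic_cycling(self, params, init_mixed):
        grid = {"r_a": [1.0, 1.4], "a": [0.5, 1.5]}
        with pytest.warns(UserWarning):
            res = select_threshold((0, 2), grid, params, init_mixed)
        row0 = res.scores[res.scores["threshold"] == 0].iloc[0]
        assert row0["similarity_to_at1"] == 1.0

    def test_memoized_scan_matches_direct_runs(self, params, init_mixed):
        grid = {"r_a": [1.0, 1.5], "a": [1.0, 2.0]}
        with pytest.warns(UserWarning):
            res = select_threshold((3, 12), grid, params, init_mixed)
        spec = ProtocolSpec(kind="at1")
        for thr in (3, 8, 12):
            sims = []
            for m_r in grid["r_a"]:
                for m_a in grid["a"]:
                    from reachat.protocols import apply_multipliers

                    p = apply_multipliers(params, {"r_a": m_r, "a": m_a})
                    t1 = run_protocol(p, init_mixed, spec.with_(kind="at1")).time_to_event
                    t2 = run_protocol(
                        p, init_mixed,
                        spec.with_(kind="at2", at2_rule="restore_index", ri_threshold=float(thr)),
                    ).time_to_event
                    sims.append(abs(t1 - t2) <= 1e-6)
            direct_similarity = float(np.mean(sims))
            row = res.scores[res.scores["threshold"] == thr].iloc[0]
            assert row["similarity_to_at1"] == pytest.approx(direct_similarity, abs=1e-12)

    def test_empty_range_rejected(self, params, init_mixed):
        with pytest.raises(ConfigurationError):
            select_threshold((5, 3), {"r_a": [1.0]}, params, init_mixed)


class TestRiDuration:
    def test_insufficient_pairs(self, params, init_mixed):
        grid = {"r_a": [1.0], "K_a": [1.0]}
        spec = ProtocolSpec(kind="at1", horizon=12.0)  # one or two cycles only
        with pytest.raises(InsufficientDataError):
            ri_duration_study(params, grid, init_mixed, spec)

    def test_duplicate_nodes_leave_correlation_unchanged(self, params, init_mixed):
        g1 = {"r_a": [0.6, 1.0, 1.4], "K_a": [1.0, 1.6]}
        g2 = {"r_a": [0.6, 1.0, 1.4, 0.6, 1.0, 1.4], "K_a": [1.0, 1.6]}
        _, rho1 = ri_duration_study(params, g1, init_mixed)
        _, rho2 = ri_duration_study(params, g2, init_mixed)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_restore_index_declines_across_cycles(self, params, init_mixed):
        out = run_protocol(params, init_mixed, ProtocolSpec(kind="at1"))
        ris = [c.ri_start for c in out.cycles]
        assert len(ris) >= 3
        assert all(b < a for a, b in zip(ris, ris[1:]))

    def test_default_grid_bounds(self):
        g = default_ri_duration_grid()
        assert g["r_a"][0] == 0.5 and g["r_a"][-1] == 2.0
        assert g["K_a"][0] == 0.8 and g["K_a"][-1] == 2.0


def _pav_decreasing(x, y):
    """Brute-force pool-adjacent-violators for a decreasing fit (test oracle)."""
    order = np.argsort(x)
    ys = list(y[order])
    ws = [1.0] * len(ys)
    blocks = [[v] for v in ys]
    # enforce non-increasing means
    means = ys[:]
    i = 0
    vals = [(v, 1.0) for v in ys]
    out = []
    for v, w in vals:
        out.append([v, w])
        while len(out) > 1 and out[-2][0] < out[-1][0]:
            v2, w2 = out.pop()
            out[-1][0] = (out[-1][0] * out[-1][1] + v2 * w2) / (out[-1][1] + w2)
            out[-1][1] += w2
    fitted = []
    for v, w in out:
        fitted.extend([v] * int(w))
    return np.asarray(x)[order], np.asarray(fitted)


class TestRiResponse:
    def test_exact_linear_corpus(self):
        ri = np.array([1.0, 3.16227766, 10.0, 31.6227766, 100.0])
        corpus = pd.DataFrame({"ri_start": ri, "dv_2day": -10.0 * np.log10(ri)})
        assert ri_response_map(corpus, 10.0) == pytest.approx(-10.0, abs=1e-9)
        assert ri_response_map(corpus, 10.0, method="linear") == pytest.approx(-10.0, abs=1e-9)

    def test_permutation_invariance(self, rng):
        ri = np.exp(rng.uniform(0, 5, 40))
        dv = -5.0 * np.log(ri) + rng.normal(0, 3, 40)
        corpus = pd.DataFrame({"ri_start": ri, "dv_2day": dv})
        v1 = ri_response_map(corpus, 20.0)
        shuffled = corpus.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert ri_response_map(shuffled, 20.0) == pytest.approx(v1, abs=1e-9)

    def test_monotone_and_matches_pav_oracle(self, params, init_mixed):
        corpus = ri_response_corpus(
            params, {"r_a": [0.8, 1.2, 1.6], "K_a": [1.0, 1.5]}, init_mixed
        )
        ris = np.asarray(corpus["ri_start"])
        lo, hi = ris.min(), ris.max()
        qs = np.linspace(lo * 1.01, hi * 0.99, 12)
        preds = [ri_response_map(corpus, q) for q in qs]
        reductions = [-p for p in preds]
        assert all(b >= a - 1e-9 for a, b in zip(reductions, reductions[1:]))
        # agree with a brute-force PAV oracle at the knots
        xs, fitted = _pav_decreasing(np.log10(ris), np.asarray(corpus["dv_2day"]))
        for xq, fq in zip(xs[::5], fitted[::5]):
            assert ri_response_map(corpus, 10**xq) == pytest.approx(fq, abs=1e-6)

    def test_extrapolation_rejected(self):
        corpus = pd.DataFrame({"ri_start": [2.0, 5.0, 9.0], "dv_2day": [-1.0, -4.0, -9.0]})
        with pytest.raises(ExtrapolationError):
            ri_response_map(corpus, 100.0)
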