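"""Two-step estimation of the restore-index switching threshold.

Step 1 (:func:`screen_plans`) simulates a small grid of three-cycle
adaptive-therapy plans that may skip the drug-withdrawal part of some cycle
("interrupt the cycle") and keeps the plans whose time-to-event is no worse
than a reference classic-adaptive-therapy run.  The restore index at each
retained plan's interruption point spans an integer range of candidate
thresholds.

Step 2 (:func:`select_threshold`) simulates reachability-based adaptive
therapy (AT2) with every integer threshold in that range over a grid of
resistant-subpopulation multipliers, scores each threshold by the mean time
gained over classic adaptive therapy (AT1) restricted to grid nodes where
AT1 underperforms continuous dosing (MTD) — the "bad outcome" cases —
normalizes by the maximum across thresholds, and picks the largest
threshold within a tolerance of the optimum (a larger threshold switches
earlier, minimizing similarity to AT1).

Two companion studies characterize the index: the correlation between the
restore index at a cycle start and the duration of that cycle
(:func:`ri_duration_study`), and the monotone map from restore index to the
two-day volume response (:func:`ri_response_map`), which converts the model
statistic into the bedside-observable switching rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import ConfigurationError, ExtrapolationError, InsufficientDataError
from .protocols import (
    ProtocolOutcome,
    ProtocolSpec,
    apply_multipliers,
    run_protocol,
)
from .tumor_model import SubpopParams, TumorState, restore_index

__all__ = [
    "PlanSpec",
    "PlanOutcome",
    "ThresholdScore",
    "ScreenResult",
    "SelectResult",
    "default_plan_grid",
    "run_plan",
    "screen_plans",
    "select_threshold",
    "ri_duration_study",
    "ri_response_corpus",
    "ri_response_map",
]


@dataclass(frozen=True)
class PlanSpec:
    """A fixed three-cycle adaptive-therapy plan.

    ``t_first_cycle`` is the absolute start time (day) of the first dosing
    block; ``dosing`` and ``withdrawal`` give the per-cycle block and
    holiday lengths (day, three cycles each).  If ``skip_withdrawal_from``
    is a cycle index (0-based), that cycle's withdrawal and all later
    cycling are skipped: dosing is continuous from that cycle's start —
    the plan "interrupts the treatment cycle".
    """

    t_first_cycle: float
    dosing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    withdrawal: tuple[float, float, float] = (4.0, 4.0, 4.0)
    skip_withdrawal_from: int | None = None

    def __post_init__(self) -> None:
        if len(self.dosing) != 3 or len(self.withdrawal) != 3:
            raise ConfigurationError("plans have exactly 3 cycles")
        if any(d < 2.0 for d in self.dosing):
            raise ConfigurationError("dosing blocks must be at least 2 days")
        if any(w < 0 for w in self.withdrawal):
            raise ConfigurationError("withdrawal durations must be non-negative")
        if self.skip_withdrawal_from is not None and not (0 <= self.skip_withdrawal_from <= 2):
            raise ConfigurationError("skip_withdrawal_from must be a cycle index 0..2")


@dataclass(frozen=True)
class PlanOutcome:
    plan: PlanSpec
    failure_time: float | None
    censored: bool
    horizon: float
    switching_ri: float | None  # restore index at the interruption point
    switch_time: float | None
    trajectory: object = None  # Trajectory of the simulated plan

    @property
    def time_to_event(self) -> float:
        return self.horizon if self.censored else float(self.failure_time)


@dataclass(frozen=True)
class ThresholdScore:
    threshold: int
    improvement_raw: float  # mean time gained (day) over AT1 on bad-outcome nodes
    improvement: float  # normalized to the maximum across thresholds
    similarity_to_at1: float  # fraction of nodes where AT2 ties AT1


@dataclass(frozen=True)
class ScreenResult:
    admissible: tuple[PlanOutcome, ...]
    switching_values: tuple[float, ...]
    ri_range: tuple[int, int] | None


@dataclass(frozen=True)
class SelectResult:
    threshold: int
    scores: pd.DataFrame
    degenerate: bool = False

    def score_rows(self) -> list[ThresholdScore]:
        return [
            ThresholdScore(
                threshold=int(r["threshold"]),
                improvement_raw=float(r["improvement_raw"]),
                improvement=float(r["improvement"]),
                similarity_to_at1=float(r["similarity_to_at1"]),
            )
            for _, r in self.scores.iterrows()
        ]


def default_plan_grid(
    t_trigger: float,
    t_first_offsets: Sequence[float] = (-4.0, 0.0, 4.0),
    dosing_days: Sequence[float] = (2.0, 3.0, 4.0),
    withdrawal_days: Sequence[float] = (2.0, 4.0, 6.0, 8.0),
) -> list[PlanSpec]:
    """Exhaustive small plan grid around a trigger-crossing time.

    Uniform per-cycle dosing/withdrawal lengths, all first-cycle start
    offsets and all skip indices (including no skip).
    """
    plans = []
    for off in t_first_offsets:
        t0 = t_trigger + off
        if t0 < 0:
            continue
        for d in dosing_days:
            for w in withdrawal_days:
                for skip in (None, 0, 1, 2):
                    plans.append(
                        PlanSpec(
                            t_first_cycle=t0,
                            dosing=(d, d, d),
                            withdrawal=(w, w, w),
                            skip_withdrawal_from=skip,
                        )
                    )
    return plans


def run_plan(
    params: SubpopParams,
    init: TumorState,
    plan: PlanSpec,
    spec: ProtocolSpec,
) -> PlanOutcome:
    """Simulate a fixed plan and detect the failure time.

    The tumor grows drug-free until ``plan.t_first_cycle``; scheduled cycles
    then run with fixed dosing/withdrawal lengths.  After the third cycle
    (or from the skipped cycle's start) dosing is continuous.  Failure uses
    the dosing-protocol rule: first time the volume reaches ``spec.v_end``
    while dosing with non-decreasing volume.
    """
    from .protocols import _Engine

    eng = _Engine(params, init, spec)
    t_first = min(plan.t_first_cycle, spec.horizon)
    # pre-treatment growth: until dosing starts the plan is indistinguishable
    # from the untreated control, so crossing the end volume before the first
    # block counts as failure
    status = eng._integrate(t_first, 0.0, events=[eng._crossing_event(spec.v_end)])
    if status == "event" and eng.t < t_first - 1e-6:
        eng.failure_time = eng.t
    elif status == "event" and eng.t < t_first:
        eng._integrate(t_first, 0.0)
    switching_ri = None
    switch_time = None
    if eng.failure_time is None and eng.t < spec.horizon:
        skipped = False
        for i in range(3):
            if plan.skip_withdrawal_from == i:
                switching_ri = restore_index(eng.state(), params)
                switch_time = eng.t
                eng.continuous_dose()
                skipped = True
                break
            _, failed = eng.dose_block(plan.dosing[i])
            if failed or eng.t >= spec.horizon:
                break
            # withdrawal: fixed length, truncated at the trigger volume — an
            # adaptive plan never deliberately lets the tumor beyond the trigger
            if eng.V < spec.v_trigger:
                eng._integrate(
                    min(eng.t + plan.withdrawal[i], spec.horizon), 0.0,
                    events=[eng._crossing_event(spec.v_trigger)],
                )
            if eng.t >= spec.horizon:
                break
        else:
            switch_time = eng.t
            eng.continuous_dose()
        if skipped:
            switch_time = eng.switch_time if eng.switch_time is not None else switch_time
    return PlanOutcome(
        plan=plan,
        failure_time=eng.failure_time,
        censored=eng.failure_time is None,
        horizon=spec.horizon,
        switching_ri=switching_ri,
        switch_time=switch_time,
        trajectory=eng.finish().trajectory,
    )


def screen_plans(
    params: SubpopParams,
    init: TumorState,
    plan_grid: Sequence[PlanSpec],
    reference: ProtocolOutcome,
    spec: ProtocolSpec | None = None,
) -> ScreenResult:
    """Keep plans at least as good as the reference classic adaptive run.

    Returns the admissible plan outcomes, the restore-index values at the
    interruption points of the admissible interrupting plans, and the
    closed integer range spanning those values (``None`` if no interrupting
    plan was admissible).
    """
    if not plan_grid:
        raise ConfigurationError("empty plan grid")
    if spec is None:
        spec = ProtocolSpec(kind="at1", horizon=reference.horizon)
    ref_t = reference.time_to_event
    admissible: list[PlanOutcome] = []
    values: list[float] = []
    for plan in plan_grid:
        out = run_plan(params, init, plan, spec)
        if out.time_to_event >= ref_t - 1e-6:
            admissible.append(out)
            if out.switching_ri is not None and math.isfinite(out.switching_ri):
                values.append(out.switching_ri)
    if not values:
        warnings.warn("no admissible interrupting plan; empty restore-index range")
        return ScreenResult(tuple(admissible), (), None)
    lo = int(math.floor(min(values)))
    hi = int(math.ceil(max(values)))
    return ScreenResult(tuple(admissible), tuple(values), (lo, hi))


def select_threshold(
    ri_range: tuple[int, int],
    sweep: dict[str, Sequence[float]],
    base: SubpopParams,
    init: TumorState,
    spec: ProtocolSpec | None = None,
    tol: float = 0.01,
    relative_to: str = "sensitive",
) -> SelectResult:
    """Score every integer threshold in ``ri_range`` on a multiplier grid.

    ``sweep`` maps resistant-parameter names to multiplier sequences (the
    reference dialect applies them to the sensitive subpopulation's typical
    values).  The chosen threshold is the largest one whose normalized
    improvement is within ``tol`` of the maximum.
    """
    lo, hi = int(ri_range[0]), int(ri_range[1])
    if hi < lo:
        raise ConfigurationError("empty threshold range")
    if not sweep or any(len(v) == 0 for v in sweep.values()):
        raise ConfigurationError("empty sweep grid")
    if spec is None:
        spec = ProtocolSpec(kind="at1")

    names = list(sweep)
    meshes = np.meshgrid(*[np.asarray(sweep[n], dtype=float) for n in names], indexing="ij")
    nodes = [dict(zip(names, vals)) for vals in zip(*[m.ravel() for m in meshes])]

    at1_t = np.empty(len(nodes))
    mtd_t = np.empty(len(nodes))
    node_params = []
    ri_seqs: list[list[float]] = []
    for i, mults in enumerate(nodes):
        p = apply_multipliers(base, mults, relative_to=relative_to)
        node_params.append(p)
        out1 = run_protocol(p, init, spec.with_(kind="at1"))
        at1_t[i] = out1.time_to_event
        ri_seqs.append([c.ri_start for c in out1.cycles])
        mtd_t[i] = run_protocol(p, init, spec.with_(kind="mtd")).time_to_event
    bad = at1_t < mtd_t - 1e-9

    # AT2 under the restore-index rule shares AT1's trajectory until the rule
    # first fires, so its outcome depends on the threshold only through the
    # index of the firing cycle; memoize per (node, firing cycle).
    caches: list[dict[int, float]] = [dict() for _ in nodes]

    def at2_time(i: int, thr: float) -> float:
        k = next((j for j, r in enumerate(ri_seqs[i]) if r < thr), None)
        if k is None:
            return float(at1_t[i])
        if k not in caches[i]:
            s2 = spec.with_(kind="at2", at2_rule="restore_index", ri_threshold=float(thr))
            caches[i][k] = run_protocol(node_params[i], init, s2).time_to_event
        return caches[i][k]

    rows = []
    for thr in range(lo, hi + 1):
        at2_t = np.array([at2_time(i, float(thr)) for i in range(len(nodes))])
        gain = at2_t - at1_t
        improvement_raw = float(np.mean(gain[bad])) if bad.any() else math.nan
        similarity = float(np.mean(np.abs(at2_t - at1_t) <= 1e-6))
        rows.append({"threshold": thr, "improvement_raw": improvement_raw, "similarity_to_at1": similarity})
    scores = pd.DataFrame(rows)

    if not bad.any():
        warnings.warn("no bad-outcome AT1 node on the grid; returning the largest threshold")
        scores["improvement"] = math.nan
        return SelectResult(threshold=hi, scores=scores, degenerate=True)

    max_raw = scores["improvement_raw"].max()
    if max_raw <= 0:
        warnings.warn("no threshold improves the bad-outcome cases; returning the largest threshold")
        scores["improvement"] = 0.0
        return SelectResult(threshold=hi, scores=scores, degenerate=True)
    scores["improvement"] = scores["improvement_raw"] / max_raw
    near = scores[scores["improvement"] >= 1.0 - tol]
    chosen = int(near["threshold"].max())
    return SelectResult(threshold=chosen, scores=scores)


def default_ri_duration_grid(n_r: int = 6, n_K: int = 6) -> dict[str, np.ndarray]:
    """Multiplier grid for the cycle-duration study: r_a 50-200%, K_a 80-200%."""
    return {"r_a": np.linspace(0.5, 2.0, n_r), "K_a": np.linspace(0.8, 2.0, n_K)}


def _at1_cycle_pairs(
    base: SubpopParams,
    sweep: dict[str, Sequence[float]],
    init: TumorState,
    spec: ProtocolSpec,
    relative_to: str,
) -> pd.DataFrame:
    names = list(sweep)
    meshes = np.meshgrid(*[np.asarray(sweep[n], dtype=float) for n in names], indexing="ij")
    rows = []
    for vals in zip(*[m.ravel() for m in meshes]):
        mults = dict(zip(names, vals))
        p = apply_multipliers(base, mults, relative_to=relative_to)
        out = run_protocol(p, init, spec.with_(kind="at1"))
        for c in out.cycles:
            row = {f"m_{n}": v for n, v in mults.items()}
            row.update(
                ri_start=c.ri_start,
                dv_2day=c.dv_2day,
                dosing_duration=c.dosing_duration,
                withdrawal_duration=c.withdrawal_duration,
                duration=c.dosing_duration + c.withdrawal_duration,
                completed=c.withdrawal_duration > 0,
            )
            rows.append(row)
    return pd.DataFrame(rows)


def ri_duration_study(
    base: SubpopParams,
    sweep: dict[str, Sequence[float]] | None = None,
    init: TumorState | None = None,
    spec: ProtocolSpec | None = None,
    relative_to: str = "sensitive",
) -> tuple[pd.DataFrame, float]:
    """Restore index at cycle start vs. cycle duration under classic cycling.

    Every completed AT1 cycle across the grid contributes one
    ``(ri_start, duration)`` pair.  Returns the pair table and the Spearman
    rank correlation between ``log10(ri_start)`` and the cycle duration.
    """
    if sweep is None:
        sweep = default_ri_duration_grid()
    if init is None:
        init = TumorState(0.0, 180.0, 20.0)
    if spec is None:
        spec = ProtocolSpec(kind="at1")
    df = _at1_cycle_pairs(base, sweep, init, spec, relative_to)
    pairs = df[df["completed"] & np.isfinite(df["ri_start"]) & (df["ri_start"] > 0)].copy()
    if len(pairs) < 10:
        raise InsufficientDataError(f"only {len(pairs)} completed cycles; need at least 10")
    pairs["log10_ri"] = np.log10(pairs["ri_start"])
    rho = float(spearmanr(pairs["log10_ri"], pairs["duration"]).statistic)
    return pairs.reset_index(drop=True), rho


def ri_response_corpus(
    base: SubpopParams,
    sweep: dict[str, Sequence[float]] | None = None,
    init: TumorState | None = None,
    spec: ProtocolSpec | None = None,
    relative_to: str = "sensitive",
) -> pd.DataFrame:
    """Paired (restore index at dosing start, volume change over the block).

    Drawn from the same AT1 sweep machinery as the cycle-duration study;
    includes incomplete cycles since the two-day response is recorded at the
    block end regardless of what follows.
    """
    if sweep is None:
        sweep = default_ri_duration_grid()
    if init is None:
        init = TumorState(0.0, 180.0, 20.0)
    if spec is None:
        spec = ProtocolSpec(kind="at1")
    df = _at1_cycle_pairs(base, sweep, init, spec, relative_to)
    df = df[np.isfinite(df["ri_start"]) & (df["ri_start"] > 0) & np.isfinite(df["dv_2day"])]
    return df[[c for c in df.columns if c.startswith("m_")] + ["ri_start", "dv_2day"]].reset_index(drop=True)


def ri_response_map(
    corpus: pd.DataFrame,
    threshold: float,
    method: str = "isotonic",
) -> float:
    """Predicted volume change over a dosing block at a restore-index value.

    Fits a monotone-decreasing relation between ``log10`` restore index and
    the signed block volume change (larger index -> larger reduction), then
    evaluates it at ``threshold``.  ``method`` is ``"isotonic"`` (default,
    pool-adjacent-violators with linear interpolation) or ``"linear"``
    (least-squares line in log restore index).

    The returned value is the signed change in mm^3 (negative = shrinkage);
    it is the experimentally observable proxy for the switching rule.
    """
    if not {"ri_start", "dv_2day"}.issubset(corpus.columns):
        raise ConfigurationError("corpus must have ri_start and dv_2day columns")
    ri = np.asarray(corpus["ri_start"], dtype=float)
    dv = np.asarray(corpus["dv_2day"], dtype=float)
    ok = np.isfinite(ri) & (ri > 0) & np.isfinite(dv)
    ri, dv = ri[ok], dv[ok]
    if len(ri) < 2:
        raise InsufficientDataError("need at least 2 corpus points")
    if not (ri.min() <= threshold <= ri.max()):
        raise ExtrapolationError(
            f"threshold {threshold} outside observed restore-index range [{ri.min():.3g}, {ri.max():.3g}]"
        )
    x = np.log10(ri)
    xq = math.log10(threshold)
    if method == "isotonic":
        from sklearn.isotonic import IsotonicRegression

        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        iso.fit(x, dv)
        return float(iso.predict([xq])[0])
    if method == "linear":
        slope, intercept = np.polyfit(x, dv, 1)
        return float(slope * xq + intercept)
    raise ConfigurationError(f"unknown method {method!r}")
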