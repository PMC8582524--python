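"""Event-driven simulation of treatment protocols with failure-time detection.

Five protocols are supported, mirroring the animal-experiment arms:

``control``
    No drug; the tumor grows freely and fails at the first crossing of the
    end-event volume (1000 mm^3 by default).
``positive_control``
    No drug until the tumor first reaches the trigger volume, then
    continuous dosing.
``mtd``
    Maximum tolerated dose: continuous dosing from treatment start.
``at1``
    Classic adaptive therapy: once the tumor reaches the trigger volume,
    cycles of a fixed dosing block (>= 2 days) followed by drug withdrawal
    until the volume regrows to the trigger.  If a dosing block fails to
    shrink the tumor, dosing becomes continuous.
``at2``
    Reachability-based adaptive therapy: as ``at1``, but the cycling is
    interrupted (continuous dosing thereafter) when a switch rule fires —
    either the restore index at a cycle start drops below a threshold, or
    the volume reduction over a dosing block is smaller than a cutoff
    (100 mm^3 by default, the experimental proxy).

Failure-time semantics: because adaptive cycling deliberately lets the tumor
return to the trigger volume (equal to the end-event volume by default),
reaching the end volume only counts as failure when it happens *while
dosing* with non-decreasing volume — progression despite drug.  The
untreated control arm fails at any crossing.

A brute-force fixed-step engine (:func:`run_protocol_fixed_step`) implements
the same rules by forward-Euler stepping with per-step rule evaluation; it
serves as an independent oracle for the event-driven engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, IntegrationError
from .tumor_model import (
    EXTINCTION_FLOOR,
    DoseSignal,
    SubpopParams,
    Trajectory,
    TumorState,
    growth_rhs,
    restore_index,
    _rhs_vec,
)

__all__ = [
    "PROTOCOL_KINDS",
    "ProtocolSpec",
    "CycleRecord",
    "ProtocolOutcome",
    "run_protocol",
    "run_protocol_fixed_step",
    "compare_protocols",
    "sweep_outcomes",
    "default_sweep_grid",
]

PROTOCOL_KINDS = ("control", "positive_control", "mtd", "at1", "at2")


@dataclass(frozen=True)
class ProtocolSpec:
    """Treatment rules for one protocol arm.

    ``v_end`` is the end-event volume and ``v_trigger`` the cycle/start
    trigger volume (both 1000 mm^3 by default).  ``dose_block`` is the
    minimum dosing duration (>= 2 day).  ``at2_rule`` selects the switch
    rule for ``at2``: ``"restore_index"`` (fires when the restore index at a
    cycle start is below ``ri_threshold``) or ``"volume_response"`` (fires
    when the volume reduction over the dosing block is smaller than
    ``dv_threshold``).  ``monitoring`` may be a grid of discrete check times
    to mimic caliper cadence; ``None`` means continuous event detection.
    """

    kind: str
    v_end: float = 1000.0
    v_trigger: float = 1000.0
    dose_block: float = 2.0
    at2_rule: str = "volume_response"
    ri_threshold: float = 15.0
    dv_threshold: float = 100.0
    horizon: float = 365.0
    monitoring: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ConfigurationError(f"unknown protocol kind {self.kind!r}")
        if not self.v_end > 0:
            raise ConfigurationError("v_end must be positive")
        if not self.v_trigger > 0:
            raise ConfigurationError("v_trigger must be positive")
        if self.dose_block < 2.0:
            raise ConfigurationError("dose_block must be at least 2 days")
        if self.at2_rule not in ("restore_index", "volume_response"):
            raise ConfigurationError(f"unknown at2 rule {self.at2_rule!r}")
        if not self.ri_threshold >= 0:
            raise ConfigurationError("ri_threshold must be non-negative")
        if not self.dv_threshold > 0:
            raise ConfigurationError("dv_threshold must be positive")
        if self.monitoring is not None:
            object.__setattr__(self, "monitoring", tuple(sorted(self.monitoring)))

    def with_(self, **updates) -> "ProtocolSpec":
        return replace(self, **updates)

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "v_end": self.v_end,
            "v_trigger": self.v_trigger,
            "dose_block": self.dose_block,
            "at2_rule": self.at2_rule,
            "ri_threshold": self.ri_threshold,
            "dv_threshold": self.dv_threshold,
            "horizon": self.horizon,
        }
        if self.monitoring is not None:
            d["monitoring"] = list(self.monitoring)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        d = dict(d)
        if "monitoring" in d and d["monitoring"] is not None:
            d["monitoring"] = tuple(d["monitoring"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ProtocolSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class CycleRecord:
    """Bookkeeping for one adaptive-therapy treatment cycle."""

    index: int
    t_start: float
    ri_start: float
    dv_2day: float
    dosing_duration: float
    withdrawal_duration: float


@dataclass(frozen=True)
class ProtocolOutcome:
    """Result of one protocol run.

    ``failure_time`` is ``None`` when the run was censored at the horizon.
    ``switch_time`` is the first time the protocol committed to continuous
    dosing (treatment start for ``mtd``; trigger crossing for
    ``positive_control``; rule-firing time for ``at1``/``at2``), or ``None``
    if it never did.
    """

    kind: str
    failure_time: float | None
    censored: bool
    horizon: float
    switch_time: float | None
    cycles: tuple[CycleRecord, ...]
    trajectory: Trajectory

    @property
    def time_to_event(self) -> float:
        """Failure time, with censored runs counted at the horizon."""
        return self.horizon if self.censored else float(self.failure_time)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "failure_time": self.failure_time,
            "censored": self.censored,
            "horizon": self.horizon,
            "switch_time": self.switch_time,
            "cycles": [vars(c) for c in self.cycles],
        }


# ---------------------------------------------------------------------------
# event-driven engine
# ---------------------------------------------------------------------------


class _Engine:
    """Accumulates integration segments and protocol bookkeeping."""

    def __init__(self, params: SubpopParams, init: TumorState, spec: ProtocolSpec,
                 rtol: float = 1e-8, atol: float = 1e-10):
        self.params = params
        self.spec = spec
        self.rtol = rtol
        self.atol = atol
        self.t = float(init.t)
        self.y = np.array([init.H, init.A], dtype=float)
        self.ts = [self.t]
        self.Hs = [float(self.y[0])]
        self.As = [float(self.y[1])]
        self.dose_intervals: list[tuple[float, float]] = []
        self.cycles: list[CycleRecord] = []
        self.switch_time: float | None = None
        self.failure_time: float | None = None

    @property
    def V(self) -> float:
        return float(self.y[0] + self.y[1])

    def state(self) -> TumorState:
        return TumorState(t=self.t, H=float(self.y[0]), A=float(self.y[1]))

    def _record(self, sol_t, sol_y) -> None:
        yy = np.clip(sol_y, 0.0, None)
        for i, tt in enumerate(sol_t):
            if tt > self.ts[-1]:
                self.ts.append(float(tt))
                self.Hs.append(float(yy[0, i]))
                self.As.append(float(yy[1, i]))

    def _integrate(self, t_to: float, c: float, events=None) -> str:
        """Integrate to ``t_to`` under constant dose ``c``.

        Returns ``"event"`` if a terminal event stopped integration,
        else ``"end"``.  Updates the current time/state and the trajectory.
        """
        if t_to <= self.t:
            return "end"
        sol = solve_ivp(
            _rhs_vec, (self.t, t_to), self.y, method="LSODA",
            rtol=self.rtol, atol=self.atol, events=events, args=(self.params, c),
        )
        if not sol.success:
            raise IntegrationError(f"integration failed at t={sol.t[-1]}: {sol.message}")
        self._record(sol.t, sol.y)
        if sol.status == 1:  # terminal event
            for te, ye in zip(sol.t_events, sol.y_events):
                if len(te):
                    self.t = float(te[0])
                    self.y = np.clip(np.asarray(ye[0], dtype=float), 0.0, None)
                    break
            if self.ts[-1] < self.t:
                self.ts.append(self.t)
                self.Hs.append(float(self.y[0]))
                self.As.append(float(self.y[1]))
            out = "event"
        else:
            self.t = float(sol.t[-1])
            self.y = np.clip(sol.y[:, -1], 0.0, None)
            out = "end"
        self.y[self.y < EXTINCTION_FLOOR] = 0.0
        return out

    def _crossing_event(self, level: float):
        def ev(t, y, *args):
            return y[0] + y[1] - level

        ev.terminal = True
        ev.direction = 1.0
        return ev

    def _dvdt(self, c: float) -> float:
        dH, dA = growth_rhs(self.state(), self.params, c)
        return dH + dA

    def grow_to(self, level: float) -> bool:
        """Drug-free growth until V crosses ``level`` (True) or horizon (False)."""
        if self.V >= level:
            return True
        status = self._integrate(self.spec.horizon, 0.0, events=[self._crossing_event(level)])
        return status == "event"

    def _check_times_after(self, t: float) -> Iterable[float]:
        assert self.spec.monitoring is not None
        for tc in self.spec.monitoring:
            if tc > t:
                yield tc

    def grow_to_monitored(self, level: float) -> bool:
        """Discrete-monitoring variant: growth ends at the first check time with V >= level."""
        if self.V >= level:
            return True
        for tc in self._check_times_after(self.t):
            if tc > self.spec.horizon:
                break
            self._integrate(tc, 0.0)
            if self.V >= level:
                return True
        self._integrate(self.spec.horizon, 0.0)
        return False

    def dose_block(self, duration: float) -> tuple[float, bool]:
        """One dosing block of ``duration`` days.

        Returns ``(dv, failed)`` where ``dv`` is the volume change over the
        block (up to the failure time if progression occurred mid-block).
        """
        v0 = self.V
        if self.V >= self.spec.v_end - 1e-9 and self._dvdt(1.0) >= 0.0:
            self.failure_time = self.t
            return 0.0, True
        t0 = self.t
        t_end = min(self.t + duration, self.spec.horizon)
        status = self._integrate(t_end, 1.0, events=[self._crossing_event(self.spec.v_end)])
        self.dose_intervals.append((t0, self.t))
        if status == "event":
            self.failure_time = self.t
            return self.V - v0, True
        return self.V - v0, False

    def continuous_dose(self) -> None:
        """Dose until failure (rising end-volume crossing) or horizon."""
        if self.switch_time is None:
            self.switch_time = self.t
        t_on = self.t
        if self.V >= self.spec.v_end - 1e-9 and self._dvdt(1.0) >= 0.0:
            self.failure_time = self.t
            return
        status = self._integrate(self.spec.horizon, 1.0, events=[self._crossing_event(self.spec.v_end)])
        self.dose_intervals.append((t_on, self.t))
        if status == "event":
            self.failure_time = self.t

    def withdraw_to_trigger(self) -> bool:
        """Drug withdrawal until V regrows to the trigger (True) or horizon (False)."""
        if self.spec.monitoring is not None:
            return self.grow_to_monitored(self.spec.v_trigger)
        if self.V >= self.spec.v_trigger:
            return True
        status = self._integrate(
            self.spec.horizon, 0.0, events=[self._crossing_event(self.spec.v_trigger)]
        )
        return status == "event"

    def finish(self) -> ProtocolOutcome:
        # normalize dose intervals (drop empty ones, merge adjacent)
        ivals: list[tuple[float, float]] = []
        for a, b in self.dose_intervals:
            if b <= a:
                continue
            if ivals and abs(a - ivals[-1][1]) < 1e-12:
                ivals[-1] = (ivals[-1][0], b)
            else:
                ivals.append((a, b))
        traj = Trajectory(
            t=np.asarray(self.ts), H=np.asarray(self.Hs), A=np.asarray(self.As),
            dose=DoseSignal(ivals),
        )
        censored = self.failure_time is None
        return ProtocolOutcome(
            kind=self.spec.kind,
            failure_time=self.failure_time,
            censored=censored,
            horizon=self.spec.horizon,
            switch_time=self.switch_time,
            cycles=tuple(self.cycles),
            trajectory=traj,
        )


def run_protocol(
    params: SubpopParams,
    init: TumorState,
    spec: ProtocolSpec,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ProtocolOutcome:
    """Simulate one protocol arm and return its outcome.

    ``init.V`` must lie below the end-event volume (treatment starts at
    grouping, well under the endpoint).  A run that reaches the horizon
    without failing is censored, not an error.
    """
    if init.V >= spec.v_end:
        raise ValueError(f"initial volume {init.V} must be below v_end={spec.v_end}")
    eng = _Engine(params, init, spec, rtol=rtol, atol=atol)

    if spec.kind == "control":
        if eng.grow_to(spec.v_end):
            eng.failure_time = eng.t
        return eng.finish()

    if spec.kind == "mtd":
        eng.continuous_dose()
        return eng.finish()

    if spec.kind == "positive_control":
        reached = eng.grow_to_monitored(spec.v_trigger) if spec.monitoring is not None else eng.grow_to(spec.v_trigger)
        if reached:
            eng.continuous_dose()
        return eng.finish()

    # adaptive arms
    reached = eng.grow_to_monitored(spec.v_trigger) if spec.monitoring is not None else eng.grow_to(spec.v_trigger)
    if not reached:
        return eng.finish()
    idx = 0
    while eng.t < spec.horizon and eng.failure_time is None:
        idx += 1
        t_start = eng.t
        ri_start = restore_index(eng.state(), params)
        if spec.kind == "at2" and spec.at2_rule == "restore_index" and ri_start < spec.ri_threshold:
            eng.switch_time = t_start
            eng.cycles.append(CycleRecord(idx, t_start, ri_start, math.nan, 0.0, 0.0))
            eng.continuous_dose()
            break
        dv, failed = eng.dose_block(spec.dose_block)
        dosing_dur = eng.t - t_start
        if failed:
            eng.cycles.append(CycleRecord(idx, t_start, ri_start, dv, dosing_dur, 0.0))
            break
        if spec.kind == "at2" and spec.at2_rule == "volume_response" and dv > -spec.dv_threshold:
            eng.cycles.append(CycleRecord(idx, t_start, ri_start, dv, dosing_dur, 0.0))
            eng.switch_time = eng.t
            eng.continuous_dose()
            break
        if dv >= 0.0:
            # progression despite a full dosing block: never withdraw again
            eng.cycles.append(CycleRecord(idx, t_start, ri_start, dv, dosing_dur, 0.0))
            eng.switch_time = eng.t
            eng.continuous_dose()
            break
        t_wd = eng.t
        regrew = eng.withdraw_to_trigger()
        eng.cycles.append(
            CycleRecord(idx, t_start, ri_start, dv, dosing_dur, eng.t - t_wd)
        )
        if not regrew:
            break
    return eng.finish()


# ---------------------------------------------------------------------------
# fixed-step brute-force oracle
# ---------------------------------------------------------------------------


def run_protocol_fixed_step(
    params: SubpopParams,
    init: TumorState,
    spec: ProtocolSpec,
    dt: float = 1e-3,
) -> ProtocolOutcome:
    """Forward-Euler protocol engine re-evaluating the rules at every step.

    Independent of the event-driven engine; intended as a slow oracle.
    Discrete monitoring grids are not supported here.
    """
    if spec.monitoring is not None:
        raise ConfigurationError("fixed-step oracle supports continuous monitoring only")
    if init.V >= spec.v_end:
        raise ValueError("initial volume must be below v_end")

    t = float(init.t)
    H, A = float(init.H), float(init.A)
    kind = spec.kind

    # mode: "grow" (no drug, waiting for trigger/end), "block" (dosing block),
    # "withdraw", "cont" (continuous dosing)
    if kind == "control":
        mode = "grow"
    elif kind == "mtd":
        mode = "cont"
    else:
        mode = "grow"

    ts = [t]
    Hs = [H]
    As = [A]
    dose_intervals: list[tuple[float, float]] = []
    cycles: list[CycleRecord] = []
    switch_time: float | None = t if kind == "mtd" else None
    failure: float | None = None
    block_t0 = block_v0 = block_ri = math.nan
    wd_t0 = math.nan
    cyc_idx = 0
    dose_on_since: float | None = t if kind == "mtd" else None

    def record():
        ts.append(t)
        Hs.append(H)
        As.append(A)

    rec_stride = max(1, int(0.5 / dt))  # trajectory stored every ~0.5 day
    step = 0
    while t < spec.horizon - 1e-12 and failure is None:
        step += 1
        c = 1.0 if mode in ("block", "cont") else 0.0
        dH, dA = growth_rhs(TumorState(t=t, H=max(H, 0.0), A=max(A, 0.0)), params, c)
        Vprev = H + A
        H = H + dt * dH
        A = A + dt * dA
        if H < EXTINCTION_FLOOR:
            H = 0.0
        if A < EXTINCTION_FLOOR:
            A = 0.0
        t = t + dt
        V = H + A
        if step % rec_stride == 0:
            record()

        if mode == "grow":
            if kind == "control":
                if V >= spec.v_end:
                    failure = t
            elif V >= spec.v_trigger:
                if kind == "positive_control":
                    mode = "cont"
                    switch_time = t
                    dose_on_since = t
                else:  # at1 / at2 first cycle
                    cyc_idx += 1
                    ri = restore_index(TumorState(t=t, H=H, A=A), params)
                    if (
                        kind == "at2"
                        and spec.at2_rule == "restore_index"
                        and ri < spec.ri_threshold
                    ):
                        cycles.append(CycleRecord(cyc_idx, t, ri, math.nan, 0.0, 0.0))
                        mode = "cont"
                        switch_time = t
                        dose_on_since = t
                    else:
                        mode = "block"
                        block_t0, block_v0, block_ri = t, V, ri
                        dose_on_since = t
        elif mode == "block":
            if V >= spec.v_end and V >= Vprev:
                failure = t
                cycles.append(CycleRecord(cyc_idx, block_t0, block_ri, V - block_v0, t - block_t0, 0.0))
            elif t - block_t0 >= spec.dose_block - 1e-12:
                dv = V - block_v0
                if kind == "at2" and spec.at2_rule == "volume_response" and dv > -spec.dv_threshold:
                    cycles.append(CycleRecord(cyc_idx, block_t0, block_ri, dv, t - block_t0, 0.0))
                    mode = "cont"
                    switch_time = t
                elif dv >= 0.0:
                    cycles.append(CycleRecord(cyc_idx, block_t0, block_ri, dv, t - block_t0, 0.0))
                    mode = "cont"
                    switch_time = t
                else:
                    mode = "withdraw"
                    wd_t0 = t
                    dose_intervals.append((dose_on_since, t))
                    dose_on_since = None
                    cycles.append(CycleRecord(cyc_idx, block_t0, block_ri, dv, t - block_t0, math.nan))
        elif mode == "withdraw":
            if V >= spec.v_trigger:
                cycles[-1] = replace(cycles[-1], withdrawal_duration=t - wd_t0)
                cyc_idx += 1
                ri = restore_index(TumorState(t=t, H=H, A=A), params)
                if (
                    kind == "at2"
                    and spec.at2_rule == "restore_index"
                    and ri < spec.ri_threshold
                ):
                    cycles.append(CycleRecord(cyc_idx, t, ri, math.nan, 0.0, 0.0))
                    mode = "cont"
                    switch_time = t
                    dose_on_since = t
                else:
                    mode = "block"
                    block_t0, block_v0, block_ri = t, V, ri
                    dose_on_since = t
        else:  # cont
            if V >= spec.v_end and V >= Vprev:
                failure = t

    if dose_on_since is not None:
        dose_intervals.append((dose_on_since, t))
    # close a dangling withdrawal record
    if cycles and isinstance(cycles[-1].withdrawal_duration, float) and math.isnan(cycles[-1].withdrawal_duration):
        cycles[-1] = replace(cycles[-1], withdrawal_duration=t - wd_t0)
    if ts[-1] < t:
        record()
    traj = Trajectory(
        t=np.asarray(ts), H=np.asarray(Hs), A=np.asarray(As),
        dose=DoseSignal([(a, b) for a, b in dose_intervals if b > a]),
    )
    return ProtocolOutcome(
        kind=kind,
        failure_time=failure,
        censored=failure is None,
        horizon=spec.horizon,
        switch_time=switch_time,
        cycles=tuple(cycles),
        trajectory=traj,
    )


# ---------------------------------------------------------------------------
# comparisons and sweeps
# ---------------------------------------------------------------------------


def compare_protocols(
    params: SubpopParams,
    init: TumorState,
    specs: Sequence[ProtocolSpec],
    reference: str | None = None,
) -> pd.DataFrame:
    """Run several protocols on the same tumor and tabulate failure times.

    ``time_gained`` is computed against the named reference kind (the first
    spec's kind if omitted).  All specs must share ``v_end`` and ``horizon``.
    """
    if not specs:
        raise ConfigurationError("no protocol specs given")
    v_ends = {s.v_end for s in specs}
    horizons = {s.horizon for s in specs}
    if len(v_ends) > 1 or len(horizons) > 1:
        raise ConfigurationError("specs must share v_end and horizon")
    reference = reference or specs[0].kind
    if reference not in {s.kind for s in specs}:
        raise ConfigurationError(f"reference kind {reference!r} not among specs")
    rows = []
    outcomes = []
    for s in specs:
        out = run_protocol(params, init, s)
        outcomes.append(out)
        rows.append(
            {
                "kind": s.kind,
                "failure_time": out.failure_time,
                "censored": out.censored,
                "time_to_event": out.time_to_event,
            }
        )
    df = pd.DataFrame(rows)
    ref_t = df.loc[df["kind"] == reference, "time_to_event"].iloc[0]
    df["time_gained"] = df["time_to_event"] - ref_t
    df.attrs["reference"] = reference
    df.attrs["outcomes"] = outcomes
    return df


def default_sweep_grid(n_r: int = 5, n_K: int = 3, n_a: int = 5) -> dict[str, np.ndarray]:
    """Resistant-parameter multiplier grid: r_a 50-150%, K_a 80-120%, a 0-200%."""
    return {
        "r_a": np.linspace(0.5, 1.5, n_r),
        "K_a": np.linspace(0.8, 1.2, n_K),
        "a": np.linspace(0.0, 2.0, n_a),
    }


def apply_multipliers(
    base: SubpopParams,
    mults: dict[str, float],
    relative_to: str = "sensitive",
) -> SubpopParams:
    """Resistant-subpopulation parameters scaled by multipliers.

    With ``relative_to="sensitive"`` (default) the multipliers act on the
    *sensitive* subpopulation's typical values: ``r_a = m * r_h``,
    ``K_a = m * K_h``, ``a = m * h``.  With ``"own"`` they scale each
    resistant parameter's own typical value.
    """
    if relative_to not in ("sensitive", "own"):
        raise ConfigurationError("relative_to must be 'sensitive' or 'own'")
    ref = {
        "r_a": base.r_h if relative_to == "sensitive" else base.r_a,
        "K_a": base.K_h if relative_to == "sensitive" else base.K_a,
        "a": base.h if relative_to == "sensitive" else base.a,
        "h": base.h,
    }
    updates = {}
    for name, m in mults.items():
        if name not in ref:
            raise ConfigurationError(f"cannot sweep parameter {name!r}")
        updates[name] = float(m) * ref[name]
    return base.with_(**updates)


def sweep_outcomes(
    base: SubpopParams,
    grid: dict[str, Sequence[float]],
    init: TumorState,
    specs: Sequence[ProtocolSpec],
    relative_to: str = "sensitive",
) -> pd.DataFrame:
    """Protocol failure times over a grid of resistant-parameter multipliers.

    Returns a tidy table with one row per (grid node, protocol kind); the
    multiplier columns are prefixed ``m_``.  The initial state is shared by
    all nodes (the reference setting is 180 mm^3 sensitive + 20 mm^3
    resistant at treatment start).
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigurationError("sweep grid must be non-empty")
    names = list(grid)
    rows = []
    meshes = np.meshgrid(*[np.asarray(grid[n], dtype=float) for n in names], indexing="ij")
    for node in zip(*[m.ravel() for m in meshes]):
        mults = dict(zip(names, node))
        p = apply_multipliers(base, mults, relative_to=relative_to)
        for s in specs:
            out = run_protocol(p, init, s)
            row = {f"m_{n}": v for n, v in mults.items()}
            row.update(
                kind=s.kind,
                failure_time=out.failure_time,
                censored=out.censored,
                time_to_event=out.time_to_event,
                switch_time=out.switch_time,
                n_cycles=len(out.cycles),
            )
            rows.append(row)
    return pd.DataFrame(rows)
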