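"""Two-subpopulation Lotka-Volterra tumor dynamics under intermittent drug pressure.

The tumor is modelled as two competing compartments: a drug-sensitive
subpopulation ``H`` and a resistant subpopulation ``A`` (volumes in mm^3,
time in days).  Each grows logistically toward its own carrying capacity and
is suppressed by the other through dimensionless competition coefficients::

    dH/dt = r_h * H * (1 - (H + a*A) / K_h) - c * E_osi * H * (1 - A/(A+H))
    dA/dt = r_a * A * (1 - (A + h*H) / K_a)

The drug (osimertinib in the motivating system) kills only the sensitive
compartment; its kill rate is scaled by the sensitive fraction
``1 - A/(A+H) = H/(A+H)``, so a tumor dominated by resistant cells barely
responds.  Dosing enters as a piecewise-constant on/off signal ``c`` with one
dose-unit standing for the single experimental dose level (20 mg/kg/day);
the dose magnitude is folded into the efficacy constant ``E_osi``.

The *restore index* quantifies how far the drug can still push the system
back toward a sensitive-dominated state: it is the ratio of the
instantaneous drug-induced reduction rate of ``H`` to the instantaneous
proliferation rate of ``A``.  A large value means a treatment holiday is
still affordable; a small value means cycling has lost its leverage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DegenerateStateError, IntegrationError

__all__ = [
    "PARAM_NAMES",
    "EXTINCTION_FLOOR",
    "SubpopParams",
    "TumorState",
    "DoseSignal",
    "Trajectory",
    "default_params",
    "growth_rhs",
    "restore_index",
    "logistic_closed_form",
    "simulate",
]

#: Canonical order of the kinetic parameters.
PARAM_NAMES = ("r_h", "r_a", "K_h", "K_a", "a", "h", "E_osi")

#: Volumes below this floor (mm^3) are treated as extinct and clamped to zero.
EXTINCTION_FLOOR = 1e-9


@dataclass(frozen=True)
class SubpopParams:
    """Kinetic constants of the two subpopulations plus drug efficacy.

    Parameters
    ----------
    r_h, r_a : float
        Intrinsic growth rates of the sensitive / resistant subpopulation
        (1/day).
    K_h, K_a : float
        Carrying capacities (mm^3).
    a : float
        Competition coefficient of the resistant subpopulation acting on the
        sensitive one (dimensionless).
    h : float
        Competition coefficient of the sensitive subpopulation acting on the
        resistant one (dimensionless).
    E_osi : float
        Drug efficacy constant on the sensitive subpopulation
        (1/(day * dose-unit)).
    """

    r_h: float
    r_a: float
    K_h: float
    K_a: float
    a: float
    h: float
    E_osi: float

    def __post_init__(self) -> None:
        for name in ("r_h", "r_a", "K_h", "K_a"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        for name in ("a", "h", "E_osi"):
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)!r}")
        for name in PARAM_NAMES:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def with_(self, **updates: float) -> "SubpopParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **updates)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "SubpopParams":
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{name: float(d[name]) for name in PARAM_NAMES})

    @classmethod
    def from_json(cls, path) -> "SubpopParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def default_params() -> SubpopParams:
    """Synthetic typical parameter values shipped with the package.

    These stand in for fitted in-vivo values (which are not part of the
    package) and are chosen so that an untreated mixed tumor progresses within
    weeks while a two-day dosing block shrinks a sensitive-dominated tumor.
    """
    from importlib.resources import files

    with files("reachat").joinpath("data/default_params.json").open() as fh:
        return SubpopParams.from_dict(json.load(fh))


@dataclass(frozen=True)
class TumorState:
    """Time-stamped subpopulation volumes.

    ``H`` is the sensitive and ``A`` the resistant compartment (mm^3); the
    observable total volume is ``V = H + A``.
    """

    t: float
    H: float
    A: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t) and math.isfinite(self.H) and math.isfinite(self.A)):
            raise ValueError("state components must be finite")
        if self.H < 0 or self.A < 0:
            raise ValueError(f"subpopulation volumes must be non-negative, got H={self.H}, A={self.A}")

    @property
    def V(self) -> float:
        return self.H + self.A


class DoseSignal:
    """Piecewise-constant drug schedule: on-intervals ``[start, stop)`` at a level.

    The default dialect is an on/off indicator (level 1.0 while dosing,
    0.0 otherwise).  ``stop`` may be ``inf`` for open-ended dosing.
    """

    def __init__(self, intervals: Iterable[tuple[float, float]] = (), level: float = 1.0):
        if level < 0:
            raise ValueError("dose level must be non-negative")
        ivals = sorted((float(a), float(b)) for a, b in intervals)
        for (a, b) in ivals:
            if not (a >= 0 and b > a):
                raise ValueError(f"bad dose interval [{a}, {b})")
        for (_, b0), (a1, _) in zip(ivals, ivals[1:]):
            if a1 < b0:
                raise ValueError("dose intervals must not overlap")
        self.intervals: tuple[tuple[float, float], ...] = tuple(ivals)
        self.level = float(level)

    @classmethod
    def off(cls) -> "DoseSignal":
        return cls(())

    @classmethod
    def continuous(cls, t_on: float = 0.0, level: float = 1.0) -> "DoseSignal":
        return cls([(t_on, math.inf)], level=level)

    def at(self, t: float) -> float:
        for a, b in self.intervals:
            if a <= t < b:
                return self.level
        return 0.0

    def switch_times(self, lo: float, hi: float) -> list[float]:
        """Sorted switch times strictly inside ``(lo, hi)``."""
        ts = set()
        for a, b in self.intervals:
            for x in (a, b):
                if lo < x < hi and math.isfinite(x):
                    ts.add(x)
        return sorted(ts)

    def encode(self) -> str:
        """Serialize to a compact string, e.g. ``"2,4|10,inf"`` ('' = never on)."""
        return "|".join(f"{a:g},{b:g}" for a, b in self.intervals)

    @classmethod
    def decode(cls, s: str, level: float = 1.0) -> "DoseSignal":
        s = (s or "").strip()
        if not s:
            return cls.off()
        ivals = []
        for chunk in s.split("|"):
            a, b = chunk.split(",")
            ivals.append((float(a), float(b)))
        return cls(ivals, level=level)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DoseSignal)
            and self.intervals == other.intervals
            and self.level == other.level
        )

    def __repr__(self) -> str:
        return f"DoseSignal({list(self.intervals)!r}, level={self.level})"


def growth_rhs(state: TumorState, params: SubpopParams, c_osi: float) -> tuple[float, float]:
    """Instantaneous growth rates ``(dH/dt, dA/dt)`` in mm^3/day.

    The drug term removes sensitive cells at rate ``c_osi * E_osi * H``
    scaled by the sensitive fraction ``H/(A+H)``; the singular factor at
    ``H + A = 0`` is defined as 1 (the term vanishes anyway since it
    multiplies ``H``).  The resistant equation does not contain the drug.
    """
    if not (math.isfinite(state.H) and math.isfinite(state.A)):
        raise ValueError("non-finite state components")
    if c_osi < 0:
        raise ValueError("c_osi must be non-negative")
    H, A = state.H, state.A
    total = H + A
    sens_frac = 1.0 if total == 0.0 else 1.0 - A / total
    dH = params.r_h * H * (1.0 - (H + params.a * A) / params.K_h)
    dH -= c_osi * params.E_osi * H * sens_frac
    dA = params.r_a * A * (1.0 - (A + params.h * H) / params.K_a)
    return dH, dA


def restore_index(state: TumorState, params: SubpopParams) -> float:
    """Ratio of drug-induced sensitive kill rate to resistant proliferation rate.

    ``RI = [E_osi * H * (1 - A/(A+H))] / [r_a * A * (1 - (h*H + A)/K_a)]``

    Returns ``+inf`` when the numerator is positive but the denominator is
    non-positive (resistant subpopulation at or above its effective
    capacity), and ``0`` when the numerator vanishes while the denominator
    does not.

    Raises
    ------
    DegenerateStateError
        If numerator and denominator both vanish (e.g. ``A = 0`` with no
        drug-susceptible mass), where the index is undefined.
    """
    H, A = state.H, state.A
    if H < 0 or A < 0 or H + A <= 0:
        raise ValueError("restore index requires H >= 0, A >= 0, H + A > 0")
    numerator = params.E_osi * H * (1.0 - A / (A + H))
    denominator = params.r_a * A * (1.0 - (params.h * H + A) / params.K_a)
    if numerator == 0.0 and denominator == 0.0:
        raise DegenerateStateError("restore index undefined: zero numerator and denominator")
    if numerator == 0.0:
        return 0.0
    if denominator <= 0.0:
        return math.inf
    return numerator / denominator


def logistic_closed_form(r: float, K: float, x0: float, t) -> float | np.ndarray:
    """Analytic logistic growth ``K / (1 + ((K - x0)/x0) e^{-r t})``.

    Serves as the exact solution of either subpopulation in the decoupled,
    drug-free limit.  ``x0 = 0`` is the absorbing state and returns 0.
    """
    if r <= 0 or K <= 0:
        raise ValueError("r and K must be positive")
    if x0 < 0:
        raise ValueError("x0 must be non-negative")
    t = np.asarray(t, dtype=float)
    if x0 == 0.0:
        out = np.zeros_like(t)
        return float(out) if out.ndim == 0 else out
    out = K / (1.0 + ((K - x0) / x0) * np.exp(-r * t))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Trajectory:
    """Simulated course: state arrays at increasing times plus the dose used."""

    t: np.ndarray
    H: np.ndarray
    A: np.ndarray
    dose: DoseSignal

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.H) == len(self.A)):
            raise ValueError("trajectory arrays must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def V(self) -> np.ndarray:
        return self.H + self.A

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "H": self.H,
                "A": self.A,
                "V": self.V,
                "c_osi": [self.dose.at(t) for t in self.t],
            }
        )

    def state_at(self, i: int) -> TumorState:
        return TumorState(t=float(self.t[i]), H=float(self.H[i]), A=float(self.A[i]))


def _rhs_vec(t: float, y: np.ndarray, params: SubpopParams, c: float) -> list[float]:
    H = y[0] if y[0] > 0.0 else 0.0
    A = y[1] if y[1] > 0.0 else 0.0
    total = H + A
    sens_frac = 1.0 if total == 0.0 else H / total
    dH = params.r_h * H * (1.0 - (H + params.a * A) / params.K_h) - c * params.E_osi * H * sens_frac
    dA = params.r_a * A * (1.0 - (A + params.h * H) / params.K_a)
    return [dH, dA]


def simulate(
    params: SubpopParams,
    init: TumorState,
    dose: DoseSignal,
    horizon: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_eval: Sequence[float] | None = None,
) -> Trajectory:
    """Integrate the model from ``init`` to ``horizon`` under a dose schedule.

    Integration restarts exactly at every dose switch time so the
    right-hand side is smooth within each segment (LSODA, stiff-capable).
    Subpopulations falling below :data:`EXTINCTION_FLOOR` are clamped to 0
    at segment boundaries; outputs are clipped to be non-negative.

    If ``t_eval`` is given, the trajectory is reported at those times (plus
    the initial time); otherwise solver-chosen points are returned.
    """
    if not horizon > init.t:
        raise ValueError("horizon must exceed the initial time")
    boundaries = [init.t] + dose.switch_times(init.t, horizon) + [horizon]
    req = None
    if t_eval is not None:
        req = np.asarray(sorted(set(float(x) for x in t_eval)), dtype=float)
        if len(req) and (req[0] < init.t or req[-1] > horizon):
            raise ValueError("t_eval must lie within [init.t, horizon]")

    ts: list[float] = [init.t]
    Hs: list[float] = [init.H]
    As: list[float] = [init.A]
    y = np.array([init.H, init.A], dtype=float)
    for ta, tb in zip(boundaries, boundaries[1:]):
        c = dose.at(0.5 * (ta + tb))
        seg_eval = None
        keep = None
        if req is not None:
            wanted = req[(req > ta) & (req <= tb)]
            # always integrate through tb so the next segment starts exactly there
            seg_eval = np.unique(np.append(wanted, tb))
            keep = np.isin(seg_eval, wanted)
        sol = solve_ivp(
            _rhs_vec,
            (ta, tb),
            y,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            t_eval=seg_eval,
            args=(params, c),
        )
        if not sol.success:
            raise IntegrationError(f"integration failed at t={sol.t[-1] if len(sol.t) else ta}: {sol.message}")
        yy = np.clip(sol.y, 0.0, None)
        for i, tt in enumerate(sol.t):
            if keep is not None and not keep[i]:
                continue
            if tt > ts[-1]:
                ts.append(float(tt))
                Hs.append(float(yy[0, i]))
                As.append(float(yy[1, i]))
        # state handed to the next segment: clamp near-extinct compartments
        y = np.clip(sol.y[:, -1], 0.0, None)
        y[y < EXTINCTION_FLOOR] = 0.0
        if req is None and ts[-1] < tb:
            ts.append(float(tb))
            Hs.append(float(y[0]))
            As.append(float(y[1]))
    return Trajectory(t=np.asarray(ts), H=np.asarray(Hs), A=np.asarray(As), dose=dose)
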