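"""Virtual-animal cohort generation with the designs the analysis assumes.

Cohorts emulate subcutaneous xenograft experiments: animals are inoculated
with sensitive cells, resistant cells, or a 9:1 sensitive:resistant mix;
each animal's kinetic parameters are drawn log-normally around the
population typical values; the tumor grows from the inoculation volume
until it enters the grouping window (220-300 mm^3 total), which defines the
animal's time origin.  Total volume is then measured by caliper a few times
per week and, for mixed tumors, subpopulation volumes by imaging every 3-4
days.  Observations carry proportional noise ``y = f * (1 + xi * eps)``.

Arms
----
``mono_H_control`` / ``mono_A_control``
    Single-subpopulation tumors, vehicle only; identify growth rate and
    carrying capacity.
``mono_H_osi`` / ``mono_A_osi``
    Single-subpopulation tumors under continuous dosing from grouping;
    the sensitive arm identifies drug efficacy, the resistant arm confirms
    the drug's absence of effect on the resistant clone.
``mixed_control`` / ``mixed_osi``
    9:1 mixed tumors with subpopulation imaging; identify the competition
    coefficients.
``therapy_cohort``
    Mixed tumors assigned to a treatment protocol; only total volume plus a
    single pre-treatment resistant-volume point are observed (the sparse
    design used for empirical-Bayes individual estimates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigurationError
from .estimation import ObservationTable, PopulationModel
from .tumor_model import DoseSignal, SubpopParams, TumorState, Trajectory, _rhs_vec, simulate

__all__ = [
    "ARMS",
    "DesignSpec",
    "VirtualAnimal",
    "default_population",
    "draw_cohort",
    "observe",
    "generate_cohort_observations",
    "caliper_volume",
    "caliper_times",
    "imaging_times",
]

ARMS = (
    "mono_H_control",
    "mono_H_osi",
    "mono_A_control",
    "mono_A_osi",
    "mixed_control",
    "mixed_osi",
    "therapy_cohort",
)

#: Default observation horizons per arm (day).  The treated sensitive-mono
#: arm is short because the tumor regresses below caliper scale within a week.
ARM_HORIZONS = {
    "mono_H_control": 30.0,
    "mono_H_osi": 7.0,
    "mono_A_control": 30.0,
    "mono_A_osi": 30.0,
    "mixed_control": 35.0,
    "mixed_osi": 35.0,
    # therapy animals are only observed pre-treatment (sparse design)
    "therapy_cohort": 7.0,
}


@dataclass(frozen=True)
class DesignSpec:
    """One experimental arm's design.

    ``init_mix`` is the sensitive:resistant inoculation ratio (9 means
    9:1).  ``grouping_window`` is the total-volume interval whose entry
    defines t = 0.  ``caliper_per_week`` caliper measurements use weekday
    offsets {0, 2, 4}; imaging alternates 3- and 4-day gaps.
    """

    arm: str
    n: int
    init_mix: float = 9.0
    grouping_window: tuple[float, float] = (220.0, 300.0)
    caliper_per_week: int = 3
    imaging_interval: float = 3.5
    horizon: float | None = None
    inoculum: float = 50.0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ConfigurationError(f"unknown arm {self.arm!r}")
        if self.n < 1:
            raise ConfigurationError("n must be at least 1")
        lo, hi = self.grouping_window
        if not (0 < lo < hi):
            raise ConfigurationError("grouping window must satisfy 0 < lo < hi")
        if self.caliper_per_week not in (2, 3):
            raise ConfigurationError("caliper_per_week must be 2 or 3")
        if self.init_mix <= 0:
            raise ConfigurationError("init_mix must be positive")

    @property
    def effective_horizon(self) -> float:
        return self.horizon if self.horizon is not None else ARM_HORIZONS[self.arm]


@dataclass(frozen=True)
class VirtualAnimal:
    id: str
    phi: SubpopParams
    init: TumorState
    arm: str
    dose: DoseSignal


def default_population(xi: float = 0.1, omega: float = 0.2) -> PopulationModel:
    """Synthetic reference population around the shipped typical values.

    All biological parameters carry inter-individual variability except the
    drug efficacy, which is a pure fixed effect.
    """
    from .tumor_model import default_params

    typ = default_params().to_dict()
    mu = {k: math.log(v) for k, v in typ.items()}
    om = {k: omega for k in typ}
    om["E_osi"] = 0.0
    return PopulationModel(mu=mu, omega=om, xi=xi)


def caliper_volume(length: float, width: float) -> float:
    """Caliper volume ``pi * length * width^2 / 6`` (mm -> mm^3).

    By caliper convention length >= width; swapped inputs are corrected
    with a warning.
    """
    import warnings

    if width <= 0 or length <= 0:
        raise ValueError("caliper dimensions must be positive")
    if width > length:
        warnings.warn("width > length; swapping to caliper convention")
        length, width = width, length
    return math.pi * length * width**2 / 6.0


def caliper_times(horizon: float, per_week: int = 3) -> np.ndarray:
    """Measurement days: weekday offsets {0, 2, 4} (or {0, 3}) each week."""
    offsets = (0.0, 2.0, 4.0) if per_week == 3 else (0.0, 3.0)
    out = []
    week = 0.0
    while week <= horizon:
        for off in offsets:
            t = week + off
            if t <= horizon:
                out.append(t)
        week += 7.0
    return np.asarray(sorted(set(out)))


def imaging_times(horizon: float) -> np.ndarray:
    """Imaging days alternating 3- and 4-day gaps: 0, 3, 7, 10, 14, ..."""
    out = [0.0]
    gaps = (3.0, 4.0)
    i = 0
    while out[-1] + gaps[i % 2] <= horizon:
        out.append(out[-1] + gaps[i % 2])
        i += 1
    return np.asarray(out)


def _grow_to_window(
    phi: SubpopParams, H0: float, A0: float, target: float, max_days: float = 365.0
) -> tuple[float, float]:
    """Drug-free growth from the inoculum until total volume reaches ``target``."""
    if H0 + A0 >= target:
        return H0, A0

    def hit(t, y, *args):
        return y[0] + y[1] - target

    hit.terminal = True
    hit.direction = 1.0
    sol = solve_ivp(
        _rhs_vec, (0.0, max_days), [H0, A0], method="LSODA",
        rtol=1e-8, atol=1e-10, events=[hit], args=(phi, 0.0),
    )
    if sol.status != 1:
        raise ConfigurationError(
            f"tumor never reached the grouping volume {target:.0f} mm^3 within {max_days} days"
        )
    y = sol.y_events[0][0]
    return float(max(y[0], 0.0)), float(max(y[1], 0.0))


def _arm_dose(arm: str) -> DoseSignal:
    if arm.endswith("_osi"):
        return DoseSignal.continuous(0.0)
    return DoseSignal.off()


def draw_cohort(
    pop: PopulationModel,
    design: DesignSpec,
    seed: int = 0,
) -> list[VirtualAnimal]:
    """Draw ``design.n`` virtual animals with log-normal individual parameters.

    Each animal's grouping volume is drawn uniformly inside the grouping
    window; the inoculum (50 mm^3 total at the design mix ratio, or pure
    for mono arms) is grown drug-free until total volume first reaches it,
    which defines the animal's t = 0 state.
    """
    rng = np.random.default_rng(seed)
    animals = []
    for i in range(design.n):
        phi = SubpopParams.from_dict(pop.draw(rng))
        if design.arm.startswith("mono_H"):
            H0, A0 = design.inoculum, 0.0
        elif design.arm.startswith("mono_A"):
            H0, A0 = 0.0, design.inoculum
        else:
            frac = design.init_mix / (design.init_mix + 1.0)
            H0, A0 = design.inoculum * frac, design.inoculum * (1.0 - frac)
        target = rng.uniform(*design.grouping_window)
        try:
            H, A = _grow_to_window(phi, H0, A0, target)
        except ConfigurationError as err:
            raise ConfigurationError(f"animal {design.arm}-{i:03d}: {err}") from err
        animals.append(
            VirtualAnimal(
                id=f"{design.arm}-{i:03d}",
                phi=phi,
                init=TumorState(0.0, H, A),
                arm=design.arm,
                dose=_arm_dose(design.arm),
            )
        )
    return animals


def observe(
    animal: VirtualAnimal,
    trajectory: Trajectory,
    design: DesignSpec,
    xi: float,
    seed: int = 0,
) -> ObservationTable:
    """Noisy observation table for one animal from its model trajectory.

    Total-volume rows at the caliper schedule and, for mixed arms,
    subpopulation rows at the imaging schedule, each perturbed
    proportionally (``y = f * (1 + xi*eps)``, floored at 0.1 mm^3).  The
    therapy arm records total volume plus a single pre-treatment
    resistant-volume point.
    """
    if xi < 0:
        raise ConfigurationError("xi must be non-negative")
    rng = np.random.default_rng(seed)
    horizon = design.effective_horizon
    t_cal = caliper_times(horizon, design.caliper_per_week)
    rows: list[tuple[float, str, float]] = []

    def traj_value(t: float, channel: str) -> float:
        j = int(np.searchsorted(trajectory.t, t))
        j = min(j, len(trajectory.t) - 1)
        if abs(trajectory.t[j] - t) > 1e-6 and j > 0 and abs(trajectory.t[j - 1] - t) <= 1e-6:
            j -= 1
        if channel == "V":
            return float(trajectory.H[j] + trajectory.A[j])
        return float(trajectory.H[j]) if channel == "H" else float(trajectory.A[j])

    for t in t_cal:
        rows.append((float(t), "V", traj_value(t, "V")))
    if animal.arm.startswith("mixed"):
        for t in imaging_times(horizon):
            rows.append((float(t), "H", traj_value(t, "H")))
            rows.append((float(t), "A", traj_value(t, "A")))
    elif animal.arm == "therapy_cohort":
        rows.append((0.0, "A", traj_value(0.0, "A")))

    df = pd.DataFrame(rows, columns=["t", "channel", "y"])
    noisy = df["y"].to_numpy() * (1.0 + xi * rng.standard_normal(len(df)))
    df["y"] = np.maximum(noisy, 0.1)
    return ObservationTable(
        id=animal.id, data=df, arm=animal.arm, dose=animal.dose, init=animal.init
    )


def generate_cohort_observations(
    pop: PopulationModel,
    design: DesignSpec,
    seed: int = 0,
) -> tuple[list[VirtualAnimal], list[ObservationTable]]:
    """Full arm pipeline: draw animals, simulate, observe.

    Deterministic given ``seed``: the cohort draw and each animal's noise
    stream use children of one seed sequence.
    """
    root = np.random.SeedSequence(seed)
    s_draw, s_noise = root.spawn(2)
    animals = draw_cohort(pop, design, seed=int(s_draw.generate_state(1)[0] % (2**31)))
    noise_seeds = s_noise.generate_state(len(animals)) % (2**31)
    horizon = design.effective_horizon
    times = set(caliper_times(horizon, design.caliper_per_week))
    times |= set(imaging_times(horizon))
    tables = []
    for animal, s in zip(animals, noise_seeds):
        traj = simulate(
            animal.phi, animal.init, animal.dose, horizon + 1e-9,
            t_eval=sorted(times | {0.0}),
        )
        tables.append(observe(animal, traj, design, xi=pop.xi, seed=int(s)))
    return animals, tables
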