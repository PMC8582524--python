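# Methods

## Model

The tumor is two competing compartments: a drug-sensitive subpopulation
`H` and a resistant subpopulation `A` (volumes in mm³, time in days),
each logistic with cross-competition, with the drug killing only sensitive
cells in proportion to the sensitive fraction:

    dH/dt = r_h H (1 − (H + a A)/K_h) − c(t) E_osi H · H/(A+H)
    dA/dt = r_a A (1 − (A + h H)/K_a)

`c(t)` is an on/off dosing indicator: the motivating system uses a single
dose level (20 mg/kg/day osimertinib in an EGFR-mutant / KRAS-mutant
non-small-cell lung cancer xenograft mixture), so the dose magnitude is
folded into the efficacy constant `E_osi` and no pharmacokinetic layer is
modelled.  The kill term's sensitive-fraction factor `H/(A+H)` encodes
reduced apparent drug leverage in resistant-dominated tumors; it is defined
as 1 at `H + A = 0`, where the term vanishes anyway.  The resistant
equation contains no drug term (the drug has no measurable effect on the
resistant clone).

**Restore index.**  The switching statistic is the ratio of the
instantaneous drug-induced reduction rate of `H` to the instantaneous
proliferation rate of `A`:

    RI = [E_osi H (1 − A/(A+H))] / [r_a A (1 − (h H + A)/K_a)]

It approximates how far the system can still be pushed back toward a
sensitive-dominated state ("reachability"): large values mean a treatment
holiday is affordable, small values mean cycling has lost its leverage.
`RI = +inf` when the denominator is non-positive (resistant compartment at
or above its effective capacity) while the numerator is positive; `RI = 0`
for a vanishing numerator; both vanishing (e.g. a resistant-free tumor with
no drug effect) is flagged as degenerate.  The dosing indicator does not
appear in the numerator; under the on/off dose dialect this only rescales
thresholds.

## Parameters and defaults

| name   | meaning                                   | unit       | default |
|--------|-------------------------------------------|------------|---------|
| r_h    | sensitive intrinsic growth rate           | 1/day      | 0.35    |
| r_a    | resistant intrinsic growth rate           | 1/day      | 0.30    |
| K_h    | sensitive carrying capacity               | mm³        | 2000    |
| K_a    | resistant carrying capacity               | mm³        | 2000    |
| a      | competition of resistant on sensitive     | –          | 0.8     |
| h      | competition of sensitive on resistant     | –          | 1.2     |
| E_osi  | drug efficacy on the sensitive clone      | 1/day      | 1.0     |

These are synthetic typical values shipped in
`src/reachat/data/default_params.json` (overridable everywhere): they are
chosen so that an untreated mixed tumor progresses within days-to-weeks,
a two-day dosing block markedly shrinks a sensitive-dominated tumor, and
with `h·K_h > K_a` the sensitive clone competitively suppresses the
resistant one — the regime adaptive therapy exploits.  They are *not*
fitted in-vivo values; the real fitted constants live in an appendix that
is not part of this package's inputs, so headline numbers that depend on
them (a specific integer threshold range, a specific chosen threshold) are
not expected to be reproduced, only the procedure and its qualitative
structure.

## Numerics

Trajectories are integrated with a stiff-capable adaptive solver (LSODA),
relative tolerance 1e-8, absolute tolerance 1e-10 mm³, with integration
restarted exactly at every dose switch so the right-hand side is smooth
within each segment.  A compartment falling below 1e-9 mm³ is clamped to
zero (prevents negative overshoot; far below any biological volume).
Fitting uses looser tolerances (1e-6/1e-8) for speed.

## Treatment protocols

All protocols start from grouping (tumor volume 220–300 mm³) and share the
end event "volume reaches 1000 mm³" and a minimum dosing block of 2 days:

- **control** — never dosed; fails at the first 1000 mm³ crossing.
- **positive control** — dosed continuously from the first time the volume
  reaches the trigger (1000 mm³ by default).
- **MTD** — dosed continuously from grouping.
- **AT1** (classic adaptive) — from the trigger, cycles of a 2-day dosing
  block then withdrawal until the volume regrows to the trigger; if a block
  fails to shrink the tumor, dosing becomes continuous.
- **AT2** (reachability-based) — as AT1 until a switch rule fires, then
  continuous dosing.  Rules: `restore_index` (RI at a cycle start below a
  threshold; simulation mode) or `volume_response` (block shrinkage smaller
  than 100 mm³; the bedside-observable proxy, and the default).

Because adaptive cycling deliberately returns the tumor to the trigger
(equal to the end volume by default), "reaching 1000 mm³" counts as
failure only *while dosing with non-decreasing volume* — progression the
drug cannot reverse — except for the control arm, which fails at any
crossing.  "As close as possible to 1000 mm³" is operationalized as the
exact continuous crossing (event detection); an optional discrete
monitoring grid mimics caliper cadence (e.g. Mon/Wed/Fri checks).  The
default horizon is 365 days; runs reaching it are censored, never errors.
An adaptive arm whose tumor fails to regrow to the trigger within the
horizon is likewise censored.

A fixed-step forward-Euler engine (`run_protocol_fixed_step`, dt = 1e-3
day, rules re-evaluated every step) is an independent oracle; the two
engines agree on failure times to well under 0.1 day across all protocol
kinds and random parameterizations.

## Threshold search

**Step 1 — candidate range.**  A grid of three-cycle plans (first block at
the trigger crossing and ±4 days; dosing 2–4 days; withdrawals 2–8 days;
every possible interruption point, including none) is simulated; plans no
worse than the reference AT1 run are kept, and the restore index at each
admissible plan's interruption point spans the closed integer range of
candidate thresholds.  Two semantics were genuinely open and are resolved
as follows: plan withdrawals are truncated at the trigger volume (an
adaptive plan never deliberately overshoots its trigger), and a tumor that
crosses the end volume before the plan's first block counts as failed
there (pre-treatment, the plan is the untreated control).  Both choices
keep the recorded switching indices on tumor states an adaptive protocol
can actually visit; without them, late-starting or overshooting plans
record indices of order 10³ taken at states beyond the end volume.

**Step 2 — integer selection.**  Every integer in the range is used as the
AT2 switching threshold across a grid of resistant-parameter multipliers
(growth rate 50–150%, carrying capacity 80–120%, competition coefficient
0–200%, each relative to the *sensitive* clone's typical values; 5×3×5
nodes by default).  The score is the mean time gained over AT1, restricted
to "bad-outcome" nodes where AT1 underperforms MTD, normalized by the
maximum across thresholds; the chosen threshold is the largest one within
1% of that maximum (a larger threshold switches earlier and is least
similar to AT1).  Because AT2's trajectory under the restore-index rule
depends on the threshold only through which cycle it first fires at, the
scan memoizes one simulation per (node, firing cycle) — exact, not an
approximation.

**Degenerate regime at the shipped defaults.**  With the default typical
values and the sensitive-heavy sweep start (180 mm³ + 20 mm³), classic
cycling never underperforms continuous dosing anywhere on the step-2 grid:
delaying or interrupting dosing always nets time when the tumor starts
sensitive-dominated, and bad-outcome cases only arise for resistant-heavy
initial compositions (which the package reproduces when started there).
Step 2 therefore takes its defined degenerate path — flagged with a
warning, returning the largest threshold in range.  The selection
machinery is exercised end-to-end and behaves non-degenerately whenever
the parameter regime provides bad-outcome nodes.

**Companion studies.**  Across an aggressiveness grid (resistant growth
rate 50–200%, capacity 80–200% of sensitive typicals), every completed AT1
cycle contributes a (RI at cycle start, cycle duration) pair; the Spearman
rank correlation between log10 RI and duration exceeds 0.98 at the
defaults, and RI at successive cycle starts declines strictly within each
course.  A monotone-decreasing isotonic fit (pool-adjacent-violators on
log10 RI; a log-linear fit is the alternative) maps RI to the two-day
volume response, converting the model statistic into the observable
switching rule.

## Population estimation

The observation model is proportional-error Gaussian,
`y = f (1 + ξ ε)`, with log-normal inter-individual parameter variability
`φ_i ~ LN(μ, ω²)`.  Full stochastic-approximation EM machinery is out of
scope; the package uses the classical sequential two-stage dialect:

1. per-animal weighted least squares (`0.5 Σ((y−f)/(ξf))²`) over the ODE
   or closed-form predictions, log-parameterized, Nelder-Mead with 8
   seeded multistarts and a ±3 log-unit sanity box around the start;
2. population moments: `μ, ω` from the per-animal log estimates, `ξ`
   pooled from standardized residuals;
3. empirical-Bayes (MAP) individual estimates under a fitted population,
   adding the prior penalty `Σ η²/(2ω²)` — usable down to the sparse
   therapy-arm design (a pre-treatment volume series plus a single
   resistant-volume point), and the basis of the shrinkage diagnostic.

Stages are conditional: mono arms give growth parameters; the treated
sensitive-mono arm gives `E_osi` with growth fixed at stage-1 typicals
(a continuously-dosed arm cannot separate kill rate from growth rate on
its own); the untreated mixed arm gives the competition coefficients
(under continuous dosing the sensitive compartment crashes within days, so
the treated mixed arm carries no usable competition signal and serves
diagnostics only).

Diagnostics follow pharmacometric practice: IWRES `(y−f)/(ξf)` (pooled
mean ≈ 0, sd ≈ 1 for a well-specified fit; refitting mixed tumors without
the competition terms shifts the mean by > 0.2, so the diagnostic detects
that misspecification), η-shrinkage `1 − sd(η)/ω` (sd convention),
computed from an EB re-fit pass — shrinkage of the two-stage fits against
their own population is identically zero by construction — and a visual
predictive check band from pointwise quantiles of simulated noisy cohorts.

## Synthetic cohorts

Virtual animals emulate the xenograft designs: parameters drawn
log-normally (`ω = 0.2` for all biological parameters; `E_osi` is a pure
fixed effect, matching the set of parameters reported to carry
inter-individual variability), inoculation at 50 mm³ total (pure or 9:1
sensitive:resistant), drug-free growth to a per-animal uniform grouping
volume in 220–300 mm³ which defines t = 0, caliper total volume on weekday
offsets {0, 2, 4}, subpopulation imaging alternating 3- and 4-day gaps,
proportional noise `y = f(1 + ξ ε)` with ξ = 0.1 shared across channels
and a 0.1 mm³ positivity floor.  Observation horizons are design choices:
30 days for mono control arms (the growth curve saturates, identifying
r and K), 7 days for the treated sensitive-mono arm (the tumor regresses
below caliper scale within a week), 35 days for mixed arms (capturing the
competitive-suppression phase that identifies the competition
coefficients), and the pre-treatment week for the therapy arm's sparse
design.  The generator does not emulate imaging detection limits, caliper
dimension pairs (only the volume formula `π·length·width²/6` is exposed),
welfare dropout, or inter-channel noise differences; recovery results on
these cohorts therefore certify the estimator under its own assumptions,
not robustness to those real-data features.

## Known limitations

- **The resistant-on-sensitive competition coefficient `a` is weakly
  identified by the fitting designs.**  At a 9:1 mix the resistant
  compartment stays near 5% of the sensitive carrying capacity, so `a·A`
  perturbs the sensitive ceiling by only ~4% — the order of the
  measurement noise.  Noise-free fits recover `a` exactly (it is
  structurally identifiable), but at ξ = 0.1 the per-animal likelihood is
  nearly flat in `a`: per-animal estimates spread over decades, and the
  two-stage population estimate misses by tens of percent at n = 12 per
  arm.  Pooling `a` as a shared fixed effect does not help: the pooled
  estimate inherits the stage-1 carrying-capacity sampling error with
  roughly `K_h`-error/⟨A⟩ ≈ 20× leverage.  This is a property of the
  design (the information is not in the data), not of the optimizer; it is
  scientifically pointed, since `a` is precisely the constant that drives
  aggressive-resistant therapy outcomes but can only be pinned down by
  designs that let the resistant clone grow large.  `h` is estimated per
  animal but its estimation noise exceeds ω at this design, so its
  population recovery is also marginal (~5–20% across cohorts).
- Two subpopulations only; no pharmacokinetics, spatial structure,
  stochastic birth–death, or resistance-protecting paracrine effects.
- The two-stage estimator reports no standard errors and no covariate or
  between-occasion structure; ω estimates absorb estimation noise and are
  biased upward for noisily-estimated parameters.
- Restore-index thresholds are dose-dialect dependent (the on/off dose
  indicator folds the dose level into `E_osi`).
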