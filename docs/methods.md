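# Methods

## Problem

During ergometer exercise, prescribing a fixed *external* load (cycling
power, W) does not guarantee a fixed *internal* load (heart rate, bpm):
cardiovascular drift, environmental stress, and day-to-day variability all
dissociate the two. A heart-rate clamp inverts the prescription — it holds
HR at a set value by continuously adjusting power. `hrclamp` simulates
that closed loop end to end: a cardiovascular plant, the
proportional-integral clamp, a human manual-adjustment baseline, and the
tracking-error metrics used to compare them.

## Plant model

The simulated participant maps power to heart rate with the simplest
model that exhibits the phenomena the clamp has to reject:

* **Steady state.** `hr_ss(P, t) = min(hr_max, hr_rest + g·P + d(t) + e_env)`
  with power gain `g` (bpm·W⁻¹), cardiovascular drift
  `d(t) = drift_rate · max(0, t − drift_onset)/60`, and an environmental
  elevation `e_env = severity · hr_elevation_per_severity` (heat/hypoxia
  dose–response; severity 0 reproduces the unmodified plant exactly).
* **Kinetics.** First-order relaxation toward `hr_ss` with time constant
  `tau`. The discrete update is the exact exponential
  `hr ← hr + (hr_ss − hr)(1 − e^{−dt/τ})`, not an Euler step, so the
  update is invariant to the tick size under constant load and `dt` is
  not a tuning knob.
* **Measurement.** Chest-strap readings are the true HR plus i.i.d.
  Gaussian noise (`noise_sd`, default 1 bpm), emitted once per 1-s tick
  (straps report at roughly 1 Hz), clamped to a physiologically
  plausible range.

Drift enters the steady-state target rather than the state directly, so
the fixed-point property (`hr = hr_ss` is invariant) stays testable.

### Reference participant and synthetic cohort

The defaults emulate a trained adult male cyclist: `hr_rest` 60,
`hr_max` 190 bpm, gain 0.45 bpm·W⁻¹, `tau` 30 s, drift onset 600 s
(drift typically appears ~10 min into constant moderate exercise), drift
rate 0.15 bpm·min⁻¹, noise 1 bpm. `sample_participant` draws cohorts
uniformly from documented ranges (`COHORT_RANGES`): rest HR 50–70, max
HR 180–200 bpm, gain 0.3–0.6 bpm·W⁻¹, tau 25–45 s, drift rate
0–0.25 bpm·min⁻¹. These ranges are modelling choices, not measured
values. The drift-rate cap keeps whole-session drift near ~12 bpm — the
upper end of what prolonged constant-load cycling produces; with drift
modelled as linear and unbounded in time, substantially larger rates
would imply physically impossible session-end heart rates and targets
unreachable at any power.

## The PI clamp

Error is defined as `e = target − measured` so positive error (HR below
target) demands more power with non-negative gains; this is the same law
as defining the error with the opposite sign and negating the gains.
The command is the absolute power

    u(t) = kp·e(t) + ki·∫e dt,

recomputed every `update_interval` (default 5 s) and held between
updates (zero-order hold). The integral uses a rectangular rule over the
update interval — the natural pairing with a zero-order hold. The
integral term carries the steady workload bias and eliminates
steady-state error under drift; a proportional-only controller provably
leaves a residual offset (tested).

**Saturation and anti-windup.** Commands are clamped to
`[p_min, p_max]`. Conditional integration rolls the integral step back
whenever the command saturates with the error pushing further into the
bound, so a long spell at `p_max` (unreachable target) does not wind the
integral up; recovery after the target drops is then governed by the
closed-loop dynamics instead of by unwinding a huge accumulator. The
acceptance suite demonstrates the difference against a naive PI
re-implementation (≤5 bpm residual two minutes after a target drop,
versus >15 bpm without anti-windup).

**Onset ramp.** Sessions start from rest with a pre-programmed power
ramp over the first `ramp_duration` = 180 s; the PI loop is bypassed
during the ramp and the manual arm of any comparison replays the
automatic arm's ramp sample-for-sample. At handover the integral is
pre-loaded with `ramp_power/ki` so the first closed-loop command is
continuous (bumpless transfer). The ramp is linear from `p_min` to
`ramp_target_power` over `ramp_rise` seconds, then holds. The reference
rise of 90 s front-loads the onset: with first-order kinetics a rise
spread over the full 180 s reaches 90% of target only around
`ramp_duration + tau` ≈ 180 s, whereas the 90-s rise reaches it near
105 s while still arriving at handover with near-zero error (no
overshoot for either arm to shed). `ramp_rise=None` gives a single
linear segment over the whole ramp. `ramp_target_power` defaults to the
plant-inverted power for the initial target — known in simulation; for
real traces it is a config input.

**Reference gains.** `kp` = 3 W·bpm⁻¹, `ki` = 0.1 W·(bpm·s)⁻¹. With the
reference plant (gain 0.45, tau 30) the linearized closed loop is
`τs² + (1+kp·g)s + ki·g`, giving a well-damped pair with ≈30-s dominant
time constant — fast enough to track 20-bpm interval transitions with a
mean error near 2 bpm, slow enough that 1-bpm sensor noise is not
amplified into power thrash (per-update noise kick ≈ 3 W against a
~140 W workload). They are repository reference values for the simulated
plant, not values transferable to human loops as-is.

Band (zone) targets are an extrapolation of the clamp: inside the band
the error is zero and the command freezes; outside, the PI law acts on
the distance to the nearest band edge.

## Manual baseline

The rater model encodes exactly the degrees of freedom practitioners
differ in: adjustment cadence (`epoch`, default 30 s), a deadband below
which no change is made (3 bpm), a fixed step (presets: "fine" 1 W,
"coarse" 5 W), Gaussian jitter on the step, and a per-epoch probability
of not acting. Between epochs power is held. No rater learning or
fatigue is modelled; how any particular human experimenter actually
chose adjustments is unknown, so these parameters are explicit
assumptions.

## Sessions, profiles, metrics

Sessions default to 60 min at 1-s ticks. Profiles are piecewise-constant
targets: constant (reference 124 bpm), intermittent (four alternating
active/passive pairs, reference 140/120 bpm; the 5-min phase duration is
an assumption — sources describing such protocols do not state one), and
band. Infeasible targets (above the plant's reach at `p_max`) complete
with a logged warning and an `infeasible` flag rather than raising.

Error metrics are computed on the *measured* HR — the only signal the
controller or a practitioner sees — and exclude the first 180 s
(the onset ramp) by convention; true-HR variants are reported for
diagnostics. `time_to_90pct` uses 0.9 × the absolute target (not 90% of
the rest-to-target delta; the convention differs between sources and
this reading is the flagged choice). RMSE ≥ MAE holds for every trace;
aggregate reports give both per-seed means and standard deviations. In
paired comparisons the two arms share a seed and hence an identical
measurement-noise sequence, so differences are due to the policy alone.

## Determinism and numerics

Every stochastic element (sensor noise, cohort sampling, rater jitter
and lapses) derives from a single seed via `numpy` `SeedSequence`
spawning; identical seeds give bit-identical traces. Session traces
round measurements and commands to 3 decimals at record time, matching
the CSV precision, so a write/read round trip preserves every metric
exactly. The zero-order hold comparison uses a 1 ns tolerance on update
boundaries to be robust to float accumulation.

## What the simulation does and does not show

The acceptance-scale runs (twenty 60-min sessions per condition) show
that the clamp as implemented tracks its target tightly on a plant whose
disturbances are slow drift, a static environmental offset and white
measurement noise, and that a coarse fixed-step rater is strictly worse
under identical conditions. Real cardiovascular dynamics include
autocorrelated noise, breathing and posture artifacts, nonlinear
HR–power relations near the extremes, and day-to-day parameter shifts —
none of which are modelled; the plant is deliberately replaceable behind
the `steady_state_hr`/`step` interface. Passing these simulations
therefore validates the control logic and the analysis pipeline, not
clamp performance on humans. Gas-exchange thresholds, oxygen-uptake or
lactate outputs, treadmill control, and real ergometer (Bluetooth/FTMS)
transport are out of scope.
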