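"""Simulated heart-rate response of a cyclist to ergometer power output.

The plant maps external load (cycling power, W) to internal load (heart
rate, bpm) with the simplest model that reproduces the phenomena a
heart-rate clamp has to cope with:

* a linear steady-state HR-vs-power relation with a hard ceiling at
  ``hr_max``;
* first-order (mono-exponential) HR kinetics with time constant ``tau``;
* cardiovascular drift — a slow HR rise at constant power that begins
  ``drift_onset`` seconds into the session;
* a dose-dependent environmental elevation of HR at fixed power
  (heat / hypoxia), via :class:`EnvironmentModifier`;
* i.i.d. Gaussian sensor noise on the measured (chest-strap) HR.

The discrete state update uses the exact solution of the first-order ODE
rather than an Euler step, so the update is invariant to the simulation
tick size under constant load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ParticipantPhysiology",
    "EnvironmentModifier",
    "PlantState",
    "COHORT_RANGES",
    "steady_state_hr",
    "step",
    "measure_hr",
    "sample_participant",
]


class ParticipantPhysiology(BaseModel):
    """Parameters of one simulated participant's HR plant.

    Units: heart rates in beats·min⁻¹, power_gain in bpm·W⁻¹, tau and
    drift_onset in seconds, drift_rate in bpm·min⁻¹, noise_sd in bpm.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    hr_rest: float = Field(default=60.0, gt=0)
    hr_max: float = Field(default=190.0, gt=0)
    power_gain: float = Field(default=0.45, gt=0)
    tau: float = Field(default=30.0, gt=0)
    drift_onset: float = Field(default=600.0, ge=0)
    drift_rate: float = Field(default=0.15, ge=0)
    noise_sd: float = Field(default=1.0, ge=0)

    @model_validator(mode="after")
    def _check_hr_order(self) -> "ParticipantPhysiology":
        if not self.hr_rest < self.hr_max:
            raise ValueError(
                f"hr_rest ({self.hr_rest}) must be below hr_max ({self.hr_max})"
            )
        return self


class EnvironmentModifier(BaseModel):
    """Dose-dependent environmental stress (heat, hypoxia).

    ``severity`` is a dimensionless dose in [0, 1]; the steady-state HR at
    a fixed power is raised by ``severity * hr_elevation_per_severity``
    bpm. ``severity = 0`` reproduces the unmodified plant exactly.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    severity: float = Field(default=0.0, ge=0.0, le=1.0)
    hr_elevation_per_severity: float = Field(default=15.0, ge=0.0)

    @property
    def hr_elevation(self) -> float:
        return self.severity * self.hr_elevation_per_severity


#: Neutral environment (no stress); module-wide default.
AMBIENT = EnvironmentModifier(severity=0.0)


@dataclass(frozen=True)
class PlantState:
    """Instantaneous plant state: time (s), noise-free HR (bpm), power (W)."""

    t: float = 0.0
    hr_true: float = 60.0
    power_applied: float = 0.0


def _drift(participant: ParticipantPhysiology, t: float) -> float:
    """Cardiovascular drift (bpm) accrued by session time ``t`` (s)."""
    return participant.drift_rate * max(0.0, t - participant.drift_onset) / 60.0


def steady_state_hr(
    participant: ParticipantPhysiology,
    power: float,
    env: EnvironmentModifier | None = None,
    t: float = 0.0,
) -> float:
    """Steady-state HR (bpm) the plant settles to at constant ``power`` (W).

    hr_ss = min(hr_max, hr_rest + power_gain·power + drift(t) + env elevation)
    """
    if power < 0:
        raise ValueError(f"power must be non-negative, got {power} W")
    env = env if env is not None else AMBIENT
    hr = (
        participant.hr_rest
        + participant.power_gain * power
        + _drift(participant, t)
        + env.hr_elevation
    )
    return min(participant.hr_max, hr)


def step(
    state: PlantState,
    participant: ParticipantPhysiology,
    power: float,
    dt: float,
    env: EnvironmentModifier | None = None,
) -> PlantState:
    """Advance the plant by ``dt`` seconds at constant ``power``.

    Exact first-order update: hr' = hr + (hr_ss − hr)·(1 − exp(−dt/tau)),
    with hr_ss evaluated at the end of the step (drift varies slowly
    relative to any sensible tick).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt} s")
    t_next = state.t + dt
    hr_ss = steady_state_hr(participant, power, env, t_next)
    alpha = 1.0 - math.exp(-dt / participant.tau)
    hr_next = state.hr_true + (hr_ss - state.hr_true) * alpha
    hr_next = min(hr_next, participant.hr_max)
    return replace(state, t=t_next, hr_true=hr_next, power_applied=power)


def measure_hr(
    state: PlantState,
    participant: ParticipantPhysiology,
    rng: np.random.Generator | int,
) -> float:
    """One chest-strap HR reading: true HR plus Gaussian sensor noise.

    Clamped to [0, hr_max + 5·noise_sd]; deterministic given the seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if participant.noise_sd == 0:
        return state.hr_true
    value = state.hr_true + rng.normal(0.0, participant.noise_sd)
    hi = participant.hr_max + 5.0 * participant.noise_sd
    return float(np.clip(value, 0.0, hi))


#: Uniform sampling ranges for the synthetic cohort, emulating trained adult
#: males on a cycle ergometer. drift_onset is fixed at 600 s (drift typically
#: appears about 10 min into constant moderate exercise). The drift-rate cap
#: of 0.25 bpm·min⁻¹ bounds whole-session drift near ~12 bpm, the upper end
#: of values reported for prolonged constant-load cycling.
COHORT_RANGES: dict[str, tuple[float, float]] = {
    "hr_rest": (50.0, 70.0),
    "hr_max": (180.0, 200.0),
    "power_gain": (0.3, 0.6),
    "tau": (25.0, 45.0),
    "drift_rate": (0.0, 0.25),
}


def sample_participant(
    rng: np.random.Generator | int,
    noise_sd: float = 1.0,
) -> ParticipantPhysiology:
    """Draw one synthetic participant from :data:`COHORT_RANGES`.

    Deterministic given the seed; every draw satisfies the physiology
    invariants (hr_rest < hr_max etc.) by construction of the ranges.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    draws = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in COHORT_RANGES.items()}
    return ParticipantPhysiology(drift_onset=600.0, noise_sd=noise_sd, **draws)
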