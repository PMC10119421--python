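"""Proportional-integral heart-rate clamp.

The clamp holds a prescribed heart rate by adjusting ergometer power:

    u(t) = kp·e(t) + ki·∫e(t)dt,   e(t) = target HR − measured HR

so a positive error (HR below target) demands more power. ``u`` is an
absolute power command; the integral term carries the steady workload
bias and eliminates steady-state error under cardiovascular drift.

Commands are recomputed on a fixed cadence (default every 5 s) and held
between updates (zero-order hold). The integral uses a rectangular rule
over the update interval. Saturation at the power bounds is handled by
conditional integration: the integral does not accumulate while the
command is pinned at a bound and the error keeps pushing into it.

Session onset is a pre-programmed linear power ramp over the first
``ramp_duration`` seconds (default 180 s); at handover the integral is
pre-loaded so the first closed-loop command is continuous (bumpless
transfer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "error",
    "update",
    "ramp_command",
    "handover_state",
    "record_ramp",
]


class ControllerConfig(BaseModel):
    """PI-clamp configuration.

    kp in W·bpm⁻¹, ki in W·(bpm·s)⁻¹, update_interval / ramp_duration in s,
    power bounds in W. ``ramp_target_power`` is the power reached by the
    onset ramp; if None it is resolved at session start as the
    plant-inverted power for the initial target HR. ``ramp_rise`` is the
    time the linear rise takes; the ramp then holds the target power
    until handover at ``ramp_duration``. The reference rise (90 s) front-
    loads the onset so HR reaches 90% of target well inside the ramp while
    still arriving at handover with near-zero error; ``ramp_rise=None``
    stretches the rise over the whole ramp.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    kp: float = Field(default=3.0, ge=0)
    ki: float = Field(default=0.1, ge=0)
    update_interval: float = Field(default=5.0, gt=0)
    p_min: float = Field(default=0.0, ge=0)
    p_max: float = Field(default=400.0, gt=0)
    ramp_duration: float = Field(default=180.0, ge=0)
    ramp_target_power: float | None = Field(default=None, ge=0)
    ramp_rise: float | None = Field(default=90.0, gt=0)

    @model_validator(mode="after")
    def _check_bounds(self) -> "ControllerConfig":
        if not self.p_min < self.p_max:
            raise ValueError(f"p_min ({self.p_min}) must be below p_max ({self.p_max})")
        if self.ramp_rise is not None and self.ramp_rise > self.ramp_duration:
            raise ValueError(
                f"ramp_rise ({self.ramp_rise}) must not exceed ramp_duration "
                f"({self.ramp_duration})"
            )
        return self


@dataclass(frozen=True)
class ControllerState:
    """integral: accumulated error·time (bpm·s); last command (W) and its time (s)."""

    integral: float = 0.0
    last_command: float = 0.0
    last_update_t: float = -math.inf


def error(measured_hr: float, target_hr: float) -> float:
    """Tracking error e = target − measured (bpm); positive error → more power."""
    for name, v in (("measured_hr", measured_hr), ("target_hr", target_hr)):
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be finite and positive, got {v}")
    return target_hr - measured_hr


def update(
    cstate: ControllerState,
    config: ControllerConfig,
    measured_hr: float,
    target_hr: float,
    t: float,
) -> tuple[ControllerState, float]:
    """One controller invocation at session time ``t`` (s).

    Inside the update interval the previous command is held unchanged.
    At an update instant the error-time integral is accumulated
    (rectangular rule), the raw PI command is clamped to [p_min, p_max],
    and the integral step is rolled back when the command saturates with
    the error pushing further into the bound (conditional integration).
    """
    if t < cstate.last_update_t:
        raise ValueError(
            f"time moved backwards: t={t} < last update at {cstate.last_update_t}"
        )
    held = t - cstate.last_update_t < config.update_interval - 1e-9
    if held:
        return cstate, cstate.last_command

    e = error(measured_hr, target_hr)
    dt = t - cstate.last_update_t
    if not math.isfinite(dt):  # first ever invocation
        dt = config.update_interval
    integral = cstate.integral + e * dt
    u = config.kp * e + config.ki * integral
    command = float(np.clip(u, config.p_min, config.p_max))
    wound_up = (u > config.p_max and e > 0) or (u < config.p_min and e < 0)
    if wound_up:
        integral = cstate.integral
    return ControllerState(integral=integral, last_command=command, last_update_t=t), command


def ramp_command(config: ControllerConfig, t: float) -> float:
    """Pre-programmed onset power (W).

    Linear from p_min at t=0 to ramp_target_power at t=ramp_rise, held
    there until ramp_duration. Only valid for 0 ≤ t < ramp_duration.
    """
    if config.ramp_target_power is None:
        raise ValueError("ramp_target_power is unresolved; set it in the config")
    if t < 0 or t >= config.ramp_duration:
        raise ValueError(
            f"ramp_command is defined on [0, {config.ramp_duration}) s, got t={t}"
        )
    rise = config.ramp_rise if config.ramp_rise is not None else config.ramp_duration
    frac = min(t / rise, 1.0)
    return config.p_min + frac * (config.ramp_target_power - config.p_min)


def handover_state(config: ControllerConfig, t: float) -> ControllerState:
    """Controller state at ramp→closed-loop handover (bumpless transfer).

    The integral is pre-loaded so that with zero error the first
    closed-loop command equals the ramp's final power.
    """
    if config.ramp_target_power is None:
        raise ValueError("ramp_target_power is unresolved; set it in the config")
    p = float(np.clip(config.ramp_target_power, config.p_min, config.p_max))
    integral = p / config.ki if config.ki > 0 else 0.0
    return ControllerState(integral=integral, last_command=p, last_update_t=t)


def record_ramp(trace) -> np.ndarray:
    """Extract the onset-ramp power schedule (one value per tick) from a
    session trace, for sample-for-sample replay in a manual-adjustment arm."""
    mask = np.asarray(trace.phase) == "ramp"
    if trace.t.size == 0 or not mask.any():
        raise ValueError("trace contains no ramp phase to record")
    return np.asarray(trace.power_applied)[mask].copy()
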