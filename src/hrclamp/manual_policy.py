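"""Simulated human manual adjustment of ergometer power.

The baseline a heart-rate clamp is compared against: an experimenter who
looks at the HR reading every ``epoch`` seconds (typically 30 s) and, if
it is off target by more than a deadband, nudges the resistance by a
fixed step (1 W "fine" or 5 W "coarse"). Rater variability enters as
Gaussian jitter on the step magnitude and as a per-epoch probability of
not acting at all. Between epochs the power is held constant — that hold
is the session loop's job, not the policy's.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["ManualPolicy", "MANUAL_PRESETS", "manual_update"]


class ManualPolicy(BaseModel):
    """Epoch-based manual adjustment rule.

    epoch in s, deadband in bpm, step and step_jitter_sd in W,
    reaction_prob in (0, 1]. Power commands are clamped to [p_min, p_max].
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    epoch: float = Field(default=30.0, gt=0)
    deadband: float = Field(default=3.0, ge=0)
    step: float = Field(default=5.0, gt=0)
    step_jitter_sd: float = Field(default=0.0, ge=0)
    reaction_prob: float = Field(default=1.0, gt=0, le=1.0)
    p_min: float = Field(default=0.0, ge=0)
    p_max: float = Field(default=400.0, gt=0)

    @model_validator(mode="after")
    def _check_bounds(self) -> "ManualPolicy":
        if not self.p_min < self.p_max:
            raise ValueError(f"p_min ({self.p_min}) must be below p_max ({self.p_max})")
        return self


#: Named step-magnitude presets for the two rater styles.
MANUAL_PRESETS: dict[str, dict[str, float]] = {
    "fine": {"step": 1.0},
    "coarse": {"step": 5.0},
}


def manual_update(
    policy: ManualPolicy,
    last_command: float,
    measured_hr: float,
    target_hr: float,
    t: float,
    rng: np.random.Generator | int,
    epoch_origin: float = 0.0,
) -> float:
    """One rater decision at an epoch boundary; returns the new power (W).

    Raises if called off-epoch: the policy only ever acts at
    ``epoch_origin + k·epoch``.
    """
    phase = (t - epoch_origin) % policy.epoch
    if min(phase, policy.epoch - phase) > 1e-6:
        raise ValueError(
            f"manual_update called off-epoch at t={t} s "
            f"(epoch {policy.epoch} s from origin {epoch_origin} s)"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    err = target_hr - measured_hr
    if abs(err) <= policy.deadband:
        return last_command
    if policy.reaction_prob < 1.0 and rng.random() > policy.reaction_prob:
        return last_command
    delta = policy.step
    if policy.step_jitter_sd > 0:
        delta += rng.normal(0.0, policy.step_jitter_sd)
    new = last_command + math.copysign(delta, err)
    return float(np.clip(new, policy.p_min, policy.p_max))
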