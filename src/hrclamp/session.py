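"""Target profiles and the closed-loop session runner.

A session ticks the HR plant at a fixed step (default 1 s, the cadence
of a chest-strap reading), samples a noisy HR measurement each tick, and
drives the ergometer power either with the PI clamp (at its 5-s command
cadence) or with the simulated manual rater (at 30-s epochs). The first
``ramp_duration`` seconds follow a pre-programmed linear power ramp; in
a comparison the manual arm replays the automatic arm's ramp
sample-for-sample so both arms share an identical onset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .controller import (
    ControllerConfig,
    ControllerState,
    handover_state,
    ramp_command,
    record_ramp,
    update,
)
from .manual_policy import ManualPolicy, manual_update
from .plant import (
    AMBIENT,
    EnvironmentModifier,
    ParticipantPhysiology,
    PlantState,
    sample_participant,
    steady_state_hr,
    step,
)

__all__ = [
    "Segment",
    "TargetProfile",
    "SimulationConfig",
    "SessionTrace",
    "ComparisonReport",
    "make_profile",
    "run_session",
    "compare_auto_manual",
]

logger = logging.getLogger("hrclamp")


@dataclass(frozen=True)
class Segment:
    """One piece of a target profile: [start_t, start_t + duration) seconds.

    Point targets have band_low == band_high; zone targets carry a band.
    """

    start_t: float
    duration: float
    band_low: float
    band_high: float

    @property
    def is_band(self) -> bool:
        return self.band_high > self.band_low


@dataclass(frozen=True)
class TargetProfile:
    """Piecewise-constant target HR (or HR band) over session time."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("profile must have at least one segment")
        t = self.segments[0].start_t
        for seg in self.segments:
            if seg.duration <= 0:
                raise ValueError(f"segment duration must be positive, got {seg.duration}")
            if seg.band_low > seg.band_high:
                raise ValueError("band_low must not exceed band_high")
            if abs(seg.start_t - t) > 1e-9:
                raise ValueError(
                    f"segments must be contiguous: expected start {t}, got {seg.start_t}"
                )
            t = seg.start_t + seg.duration

    @property
    def duration(self) -> float:
        last = self.segments[-1]
        return last.start_t + last.duration - self.segments[0].start_t

    def band_at(self, t: float) -> tuple[float, float]:
        """Target band (low, high) at session time ``t``; point targets
        return (hr, hr). Times past the end use the final segment."""
        for seg in self.segments:
            if seg.start_t <= t < seg.start_t + seg.duration:
                return seg.band_low, seg.band_high
        last = self.segments[-1]
        if t >= last.start_t:
            return last.band_low, last.band_high
        raise ValueError(f"t={t} precedes the profile start")


def make_profile(kind: str, **params) -> TargetProfile:
    """Build a target profile.

    kind="constant": target_hr, duration (s).
    kind="intermittent": n_intervals active/passive pairs of
        (active_hr, active_duration) then (passive_hr, passive_duration);
        defaults 140/120 bpm, 300 s per phase, 4 intervals.
    kind="band": band_low, band_high, duration (s).
    """
    if kind == "constant":
        hr = float(params["target_hr"])
        dur = float(params["duration"])
        return TargetProfile(segments=(Segment(0.0, dur, hr, hr),))
    if kind == "intermittent":
        active = float(params.get("active_hr", 140.0))
        passive = float(params.get("passive_hr", 120.0))
        n = int(params.get("n_intervals", 4))
        d_act = float(params.get("active_duration", 300.0))
        d_pas = float(params.get("passive_duration", 300.0))
        if n <= 0:
            raise ValueError(f"n_intervals must be positive, got {n}")
        segs: list[Segment] = []
        t = 0.0
        for _ in range(n):
            segs.append(Segment(t, d_act, active, active))
            t += d_act
            segs.append(Segment(t, d_pas, passive, passive))
            t += d_pas
        return TargetProfile(segments=tuple(segs))
    if kind == "band":
        lo = float(params["band_low"])
        hi = float(params["band_high"])
        dur = float(params["duration"])
        if not lo < hi:
            raise ValueError(f"band_low ({lo}) must be below band_high ({hi})")
        return TargetProfile(segments=(Segment(0.0, dur, lo, hi),))
    raise ValueError(f"unknown profile kind {kind!r}")


class SimulationConfig(BaseModel):
    """Tick size and session duration. duration=None runs the full profile."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    dt: float = Field(default=1.0, gt=0)
    duration: float | None = Field(default=None, gt=0)


@dataclass
class SessionTrace:
    """Per-tick record of one session.

    Arrays share one length; t is strictly increasing. ``target`` is the
    control target at each tick (for band segments: the measured HR
    clamped into the band, so target − measured is the distance to the
    band). ``phase`` is "ramp" or "closed_loop"; ``arm`` is "auto" or
    "manual".
    """

    t: np.ndarray
    target: np.ndarray
    hr_true: np.ndarray
    hr_measured: np.ndarray
    power_command: np.ndarray
    power_applied: np.ndarray
    phase: np.ndarray
    arm: str = "auto"
    infeasible_fraction: float = 0.0
    seed: int | None = None

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def infeasible(self) -> bool:
        """True when the target exceeded the plant's reach at p_max for
        more than 10% of ticks."""
        return self.infeasible_fraction > 0.10


def _resolve_controller(
    config: ControllerConfig,
    participant: ParticipantPhysiology,
    profile: TargetProfile,
    env: EnvironmentModifier,
) -> ControllerConfig:
    """Fill in ramp_target_power if unset: plant-inverted power for the
    initial target, clipped to the power bounds."""
    if config.ramp_target_power is not None:
        return config
    lo, hi = profile.band_at(0.0)
    target0 = 0.5 * (lo + hi)
    p_star = (target0 - participant.hr_rest - env.hr_elevation) / participant.power_gain
    p_ramp = float(np.clip(p_star, config.p_min, config.p_max))
    return config.model_copy(update={"ramp_target_power": p_ramp})


def run_session(
    participant: ParticipantPhysiology,
    env: EnvironmentModifier | None,
    profile: TargetProfile,
    control: ControllerConfig | ManualPolicy,
    sim: SimulationConfig | None = None,
    rng_seed: int = 0,
    ramp_schedule: np.ndarray | None = None,
) -> SessionTrace:
    """Run one closed-loop session and return its complete trace.

    ``control`` selects the arm: a :class:`ControllerConfig` runs the PI
    clamp, a :class:`ManualPolicy` the simulated rater. A manual arm may
    replay a recorded ``ramp_schedule`` (one power value per tick); when
    none is given it follows the same linear onset ramp the clamp uses,
    without the overshoot factor. Fully reproducible from ``rng_seed``.

    An infeasible target (above the plant's reach at p_max) completes
    with a logged warning and sets ``infeasible_fraction`` on the trace.
    """
    env = env if env is not None else AMBIENT
    sim = sim if sim is not None else SimulationConfig()
    dt = sim.dt
    duration = sim.duration if sim.duration is not None else profile.duration
    if profile.duration < duration - 1e-9:
        raise ValueError(
            f"profile ({profile.duration} s) does not cover the session ({duration} s)"
        )
    n = int(round(duration / dt))

    is_manual = isinstance(control, ManualPolicy)
    if is_manual:
        policy = control
        p_min, p_max = policy.p_min, policy.p_max
        ramp_len = 180.0
        if ramp_schedule is None:
            lo, hi = profile.band_at(0.0)
            target0 = 0.5 * (lo + hi)
            p_end = (target0 - participant.hr_rest - env.hr_elevation) / participant.power_gain
            p_end = float(np.clip(p_end, p_min, p_max))
            k_ramp = int(round(ramp_len / dt))
            rise = min(90.0, ramp_len)
            frac = np.minimum(np.arange(k_ramp) * dt / rise, 1.0)
            ramp_schedule = p_min + frac * (p_end - p_min)
        else:
            ramp_schedule = np.asarray(ramp_schedule, dtype=float)
        n_ramp = ramp_schedule.size
        ramp_len = n_ramp * dt
    else:
        cfg = _resolve_controller(control, participant, profile, env)
        p_min, p_max = cfg.p_min, cfg.p_max
        ramp_len = cfg.ramp_duration
        n_ramp = int(round(ramp_len / dt))

    ss = np.random.SeedSequence(rng_seed)
    meas_rng, policy_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    noise = (
        meas_rng.normal(0.0, participant.noise_sd, size=n)
        if participant.noise_sd > 0
        else np.zeros(n)
    )
    meas_hi = participant.hr_max + 5.0 * participant.noise_sd

    t_arr = np.empty(n)
    target_arr = np.empty(n)
    hr_true_arr = np.empty(n)
    hr_meas_arr = np.empty(n)
    cmd_arr = np.empty(n)
    phase_arr = np.empty(n, dtype=object)

    state = PlantState(t=0.0, hr_true=participant.hr_rest, power_applied=0.0)
    cstate = ControllerState(last_command=p_min)
    command = p_min
    infeasible_ticks = 0

    for k in range(n):
        t = k * dt
        lo, hi = profile.band_at(t)
        hr_meas = state.hr_true + noise[k]
        hr_meas = float(min(max(hr_meas, 0.0), meas_hi))
        hr_meas = round(hr_meas, 3)
        # band semantics: inside the band there is nothing to correct
        target = float(min(max(hr_meas, lo), hi))

        in_ramp = k < n_ramp
        if in_ramp:
            command = float(ramp_schedule[k]) if is_manual else ramp_command(cfg, t)
            command = float(np.clip(command, p_min, p_max))
        elif is_manual:
            if k == n_ramp:
                command = float(ramp_schedule[-1]) if n_ramp else p_min
            rel = t - ramp_len
            if rel >= 0 and abs(rel - round(rel / policy.epoch) * policy.epoch) < dt / 2:
                command = manual_update(
                    policy, command, hr_meas, target, t, policy_rng, epoch_origin=ramp_len
                )
        else:
            if k == n_ramp:
                cstate = handover_state(cfg, t)
                command = cstate.last_command
            prev = command
            cstate, command = update(cstate, cfg, hr_meas, target, t)
            if command != prev:
                logger.debug(
                    "t=%.0fs target=%.1f meas=%.1f -> command %.1f W", t, target, hr_meas, command
                )

        if steady_state_hr(participant, p_max, env, t) < lo:
            infeasible_ticks += 1

        t_arr[k] = t
        target_arr[k] = round(target, 3)
        hr_true_arr[k] = round(state.hr_true, 3)
        hr_meas_arr[k] = hr_meas
        cmd_arr[k] = round(command, 3)
        phase_arr[k] = "ramp" if in_ramp else "closed_loop"

        state = step(state, participant, command, dt, env)

    frac = infeasible_ticks / n if n else 0.0
    if frac > 0.10:
        logger.warning(
            "target unreachable at p_max for %.0f%% of ticks; session completed anyway",
            100 * frac,
        )
    return SessionTrace(
        t=t_arr,
        target=target_arr,
        hr_true=hr_true_arr,
        hr_measured=hr_meas_arr,
        power_command=cmd_arr,
        power_applied=cmd_arr.copy(),
        phase=phase_arr,
        arm="manual" if is_manual else "auto",
        infeasible_fraction=frac,
        seed=rng_seed,
    )


@dataclass
class ComparisonReport:
    """Per-seed and aggregate tracking error for auto vs manual arms.

    RMSE (bpm) excludes the first ``exclude_first`` seconds; the manual
    arm replays the automatic arm's onset ramp sample-for-sample.
    """

    seeds: list[int]
    auto_rmse: list[float]
    manual_rmse: list[float]
    infeasible_seeds: list[int] = field(default_factory=list)
    exclude_first: float = 180.0

    def to_dict(self) -> dict:
        a, m = np.asarray(self.auto_rmse), np.asarray(self.manual_rmse)
        sd = lambda x: float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        return {
            "schema_version": 1,
            "exclude_first_s": self.exclude_first,
            "n_seeds": len(self.seeds),
            "per_seed": [
                {"seed": s, "auto_rmse_bpm": ar, "manual_rmse_bpm": mr}
                for s, ar, mr in zip(self.seeds, self.auto_rmse, self.manual_rmse)
            ],
            "auto": {"rmse_mean_bpm": float(a.mean()), "rmse_sd_bpm": sd(a)},
            "manual": {"rmse_mean_bpm": float(m.mean()), "rmse_sd_bpm": sd(m)},
            "infeasible_seeds": self.infeasible_seeds,
        }


def compare_auto_manual(
    participant: ParticipantPhysiology | None,
    env: EnvironmentModifier | None,
    profile: TargetProfile,
    controller_cfg: ControllerConfig,
    policy: ManualPolicy,
    n_seeds: int = 20,
    seeds: list[int] | None = None,
    sim: SimulationConfig | None = None,
    exclude_first: float = 180.0,
) -> ComparisonReport:
    """Paired auto-vs-manual comparison over a seed ensemble.

    For each seed: run the PI-clamp session, record its onset ramp,
    replay that ramp in the manual session (same seed, hence the same
    measurement-noise sequence), and compute RMSE excluding the first
    ``exclude_first`` seconds for both arms. ``participant=None`` samples
    a fresh synthetic participant per seed.
    """
    from .metrics import rmse  # local import to avoid a cycle

    if n_seeds < 1:
        raise ValueError("n_seeds must be at least 1")
    if seeds is None:
        seeds = list(range(1, n_seeds + 1))
    report = ComparisonReport(seeds=[], auto_rmse=[], manual_rmse=[], exclude_first=exclude_first)
    for seed in seeds:
        p = participant if participant is not None else sample_participant(seed)
        auto = run_session(p, env, profile, controller_cfg, sim=sim, rng_seed=seed)
        schedule = record_ramp(auto)
        manual = run_session(
            p, env, profile, policy, sim=sim, rng_seed=seed, ramp_schedule=schedule
        )
        report.seeds.append(seed)
        report.auto_rmse.append(rmse(auto, exclude_first=exclude_first))
        report.manual_rmse.append(rmse(manual, exclude_first=exclude_first))
        if auto.infeasible or manual.infeasible:
            report.infeasible_seeds.append(seed)
    return report
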