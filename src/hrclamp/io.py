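"""Trace persistence and run configuration.

Traces are plain CSV with the header

    t_s,target_bpm,hr_true_bpm,hr_meas_bpm,power_cmd_w,power_applied_w,phase,arm

floats at three decimals; diff-able and importable anywhere. Run
configuration is YAML or JSON validated against a strict schema (unknown
keys rejected) before any simulation starts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .controller import ControllerConfig
from .manual_policy import ManualPolicy
from .plant import EnvironmentModifier, ParticipantPhysiology
from .session import SessionTrace, SimulationConfig, TargetProfile, make_profile

__all__ = [
    "TRACE_COLUMNS",
    "write_trace",
    "read_trace",
    "ProfileConfig",
    "RunConfig",
    "load_config",
    "default_config",
    "config_to_yaml",
]

TRACE_COLUMNS = [
    "t_s",
    "target_bpm",
    "hr_true_bpm",
    "hr_meas_bpm",
    "power_cmd_w",
    "power_applied_w",
    "phase",
    "arm",
]


def write_trace(trace: SessionTrace, path: str | Path) -> Path:
    """Write a session trace as CSV (floats at 3 decimals)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "t_s": trace.t,
            "target_bpm": trace.target,
            "hr_true_bpm": trace.hr_true,
            "hr_meas_bpm": trace.hr_measured,
            "power_cmd_w": trace.power_command,
            "power_applied_w": trace.power_applied,
            "phase": trace.phase,
            "arm": trace.arm,
        }
    )
    df.to_csv(path, index=False, float_format="%.3f")
    return path


def read_trace(path: str | Path) -> SessionTrace:
    """Read a trace CSV back into a :class:`SessionTrace`.

    Validates the header and strictly increasing time; a trailing blank
    line is tolerated. Metric values are preserved exactly through a
    write/read round trip.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing columns {missing} (line 1); expected header "
            f"{','.join(TRACE_COLUMNS)}"
        )
    t = df["t_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +3: 1-based line numbers, one header line, diff offset
        raise ValueError(f"{path}: non-monotonic time at line {int(bad[0]) + 3}")
    arms = df["arm"].unique()
    arm = str(arms[0]) if len(arms) == 1 else "mixed"
    return SessionTrace(
        t=t,
        target=df["target_bpm"].to_numpy(dtype=float),
        hr_true=df["hr_true_bpm"].to_numpy(dtype=float),
        hr_measured=df["hr_meas_bpm"].to_numpy(dtype=float),
        power_command=df["power_cmd_w"].to_numpy(dtype=float),
        power_applied=df["power_applied_w"].to_numpy(dtype=float),
        phase=df["phase"].to_numpy(dtype=object),
        arm=arm,
    )


class ProfileConfig(BaseModel):
    """Declarative target profile: kind plus its parameters."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    kind: str = "constant"
    target_hr: float | None = 124.0
    duration: float | None = 3600.0
    active_hr: float = 140.0
    passive_hr: float = 120.0
    n_intervals: int = 4
    active_duration: float = 300.0
    passive_duration: float = 300.0
    band_low: float | None = None
    band_high: float | None = None

    def build(self) -> TargetProfile:
        if self.kind == "constant":
            return make_profile("constant", target_hr=self.target_hr, duration=self.duration)
        if self.kind == "intermittent":
            return make_profile(
                "intermittent",
                active_hr=self.active_hr,
                passive_hr=self.passive_hr,
                n_intervals=self.n_intervals,
                active_duration=self.active_duration,
                passive_duration=self.passive_duration,
            )
        if self.kind == "band":
            return make_profile(
                "band", band_low=self.band_low, band_high=self.band_high, duration=self.duration
            )
        raise ValueError(f"unknown profile kind {self.kind!r}")


class RunConfig(BaseModel):
    """Full run configuration: participant, environment, profile,
    controller, manual policy, and simulation settings."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    schema_version: int = 1
    participant: ParticipantPhysiology = Field(default_factory=ParticipantPhysiology)
    environment: EnvironmentModifier = Field(default_factory=EnvironmentModifier)
    profile: ProfileConfig = Field(default_factory=ProfileConfig)
    controller: ControllerConfig = Field(default_factory=ControllerConfig)
    manual: ManualPolicy = Field(default_factory=ManualPolicy)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)


def default_config() -> RunConfig:
    """The reference configuration used throughout the documentation."""
    return RunConfig()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return RunConfig.model_validate(data)


def config_to_yaml(config: RunConfig) -> str:
    """Serialize a config to YAML; re-reading it reproduces the run exactly."""
    return yaml.safe_dump(config.model_dump(), sort_keys=False)
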