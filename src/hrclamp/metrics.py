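"""Tracking-quality and external-load summaries for session traces.

All error metrics are defined on the *measured* HR — the signal the
controller and the practitioner actually see — and, unless stated
otherwise, exclude the onset ramp (first 180 s by convention, matching
how clamped-session tracking error is reported). True-HR variants are
provided for simulation diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "TrackingMetrics",
    "rmse",
    "mae",
    "mean_tracking_error",
    "time_to_90pct",
    "steady_state_offset",
    "pct_time_in_band",
    "load_summary",
    "compute_metrics",
]


def _errors(trace, exclude_first: float, measured: bool = True) -> np.ndarray:
    if trace.t.size == 0:
        raise ValueError("empty trace")
    mask = trace.t >= exclude_first
    if not mask.any():
        raise ValueError(
            f"exclude_first={exclude_first} s leaves no samples "
            f"(trace spans {trace.t[0]}–{trace.t[-1]} s)"
        )
    hr = trace.hr_measured if measured else trace.hr_true
    return hr[mask] - trace.target[mask]


def rmse(trace, exclude_first: float = 180.0, measured: bool = True) -> float:
    """Root-mean-square HR tracking error (bpm) over t ≥ exclude_first."""
    e = _errors(trace, exclude_first, measured)
    return float(np.sqrt(np.mean(e**2)))


def mae(trace, exclude_first: float = 180.0, measured: bool = True) -> float:
    """Mean absolute HR tracking error (bpm) over t ≥ exclude_first."""
    return float(np.mean(np.abs(_errors(trace, exclude_first, measured))))


#: Mean tracking error, the conventional name for the mean absolute error.
mean_tracking_error = mae


def time_to_90pct(trace, target_hr: float | None = None) -> float | None:
    """First time (s) measured HR reaches 90% of the target HR.

    ``target_hr`` defaults to the target at the start of the trace; the
    threshold is 0.9 × the absolute target. Returns None if never reached.
    """
    if trace.t.size == 0:
        raise ValueError("empty trace")
    if target_hr is None:
        target_hr = float(trace.target[0])
    threshold = 0.9 * target_hr
    idx = np.nonzero(trace.hr_measured >= threshold)[0]
    if idx.size == 0:
        return None
    return float(trace.t[idx[0]])


def steady_state_offset(trace, window: float = 600.0, measured: bool = True) -> float:
    """Mean |target − HR| (bpm) over the final ``window`` seconds."""
    if trace.t.size == 0:
        raise ValueError("empty trace")
    span = trace.t[-1] - trace.t[0]
    if window > span + 1e-9:
        raise ValueError(f"window {window} s exceeds trace span {span} s")
    start = trace.t[-1] - window
    mask = trace.t >= start
    hr = trace.hr_measured if measured else trace.hr_true
    return float(np.mean(np.abs(hr[mask] - trace.target[mask])))


def pct_time_in_band(trace, k: float = 2.0, exclude_first: float = 180.0) -> float:
    """Percentage of time with |error| ≤ k bpm over t ≥ exclude_first."""
    e = _errors(trace, exclude_first)
    return float(100.0 * np.mean(np.abs(e) <= k))


def load_summary(trace) -> tuple[float, float]:
    """External load: (mean power, W; total work, kJ).

    Work is the trapezoidal integral of applied power over time.
    """
    if trace.t.size == 0:
        return 0.0, 0.0
    mean_power = float(np.mean(trace.power_applied))
    if trace.t.size < 2:
        return mean_power, 0.0
    work_kj = float(np.trapezoid(trace.power_applied, trace.t) / 1000.0)
    return mean_power, work_kj


@dataclass(frozen=True)
class TrackingMetrics:
    """Summary of one session's tracking quality and external load.

    rmse/mae/mean_error in bpm (rmse ≥ mae always); time_to_90pct in s
    (None if the threshold was never reached); steady_state_offset is the
    mean |error| over the final 10 min; pct_time_in_band the share of
    time within ±2 bpm of target; mean_power in W and total_work in kJ.
    rmse_true is the same RMSE on the noise-free HR.
    """

    rmse: float
    mae: float
    mean_error: float
    mean_tracking_error: float
    time_to_90pct: float | None
    steady_state_offset: float
    pct_time_in_band: float
    mean_power: float
    total_work: float
    rmse_true: float

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(
    trace,
    exclude_first: float = 180.0,
    offset_window: float = 600.0,
    band_k: float = 2.0,
) -> TrackingMetrics:
    """All tracking and load metrics for one trace."""
    e = _errors(trace, exclude_first)
    mean_power, total_work = load_summary(trace)
    window = min(offset_window, trace.t[-1] - trace.t[0])
    return TrackingMetrics(
        rmse=float(np.sqrt(np.mean(e**2))),
        mae=float(np.mean(np.abs(e))),
        mean_error=float(np.mean(e)),
        mean_tracking_error=float(np.mean(np.abs(e))),
        time_to_90pct=time_to_90pct(trace),
        steady_state_offset=steady_state_offset(trace, window=window),
        pct_time_in_band=pct_time_in_band(trace, k=band_k, exclude_first=exclude_first),
        mean_power=mean_power,
        total_work=total_work,
        rmse_true=rmse(trace, exclude_first=exclude_first, measured=False),
    )
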