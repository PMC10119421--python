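"""PI clamp: error law, zero-order hold, integral action, anti-windup, ramp."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrclamp import (
    ControllerConfig,
    ControllerState,
    error,
    handover_state,
    make_profile,
    ramp_command,
    record_ramp,
    run_session,
    update,
)


class TestError:
    @pytest.mark.parametrize(
        "measured, target, expected",
        [(124.0, 124.0, 0.0), (120.0, 124.0, 4.0), (130.0, 120.0, -10.0)],
    )
    def test_sign_convention(self, measured, target, expected):
        """Positive error (HR below target) demands more power."""
        assert error(measured, target) == expected

    @pytest.mark.parametrize("bad", [math.nan, math.inf, -5.0, 0.0])
    def test_nonfinite_or_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            error(bad, 124.0)
        with pytest.raises(ValueError):
            error(124.0, bad)


def run_updates(cfg, pairs, state=None):
    """Drive update() through (t, measured) pairs at a fixed target of 124."""
    state = state if state is not None else ControllerState(last_command=cfg.p_min, last_update_t=0.0)
    commands = []
    for t, meas in pairs:
        state, cmd = update(state, cfg, meas, 124.0, t)
        commands.append(cmd)
    return state, commands


class TestUpdate:
    def test_zero_error_zero_integral_gives_minimum_power(self):
        cfg = ControllerConfig(kp=2.0, ki=0.05)
        _, cmds = run_updates(cfg, [(t, 124.0) for t in range(5, 65, 5)])
        assert all(c == cfg.p_min for c in cmds)

    def test_rectangular_integral_closed_form(self):
        # constant +10 bpm error over 60 s of 5-s updates:
        # u = 2*10 + 0.05*(10*60) = 50 W
        cfg = ControllerConfig(kp=2.0, ki=0.05, update_interval=5.0)
        state, cmds = run_updates(cfg, [(t, 114.0) for t in range(5, 65, 5)])
        assert state.integral == pytest.approx(10.0 * 60.0)
        assert cmds[-1] == pytest.approx(50.0)

    def test_zero_order_hold_between_updates(self):
        cfg = ControllerConfig(kp=2.0, ki=0.05, update_interval=5.0)
        state = ControllerState(last_command=30.0, last_update_t=10.0)
        for t in (11.0, 12.5, 14.9):
            new_state, cmd = update(state, cfg, 100.0, 124.0, t)
            assert cmd == 30.0
            assert new_state == state  # untouched inside the interval

    def test_anti_windup_freezes_integral_while_saturated(self):
        cfg = ControllerConfig(kp=2.0, ki=0.05, p_max=100.0, update_interval=5.0)
        state, cmds = run_updates(cfg, [(t, 80.0) for t in range(5, 305, 5)])
        assert all(c <= 100.0 for c in cmds)
        assert cmds[-1] == 100.0
        # brute-force the conditional-integration rule: integral accumulates
        # only until the command first pins at p_max
        ref = ControllerState(last_command=cfg.p_min, last_update_t=0.0)
        integral = 0.0
        for t in range(5, 305, 5):
            e = 124.0 - 80.0
            candidate = integral + e * 5.0
            u = cfg.kp * e + cfg.ki * candidate
            if not (u > cfg.p_max and e > 0):
                integral = candidate
        assert state.integral == pytest.approx(integral)

    def test_time_moving_backwards_rejected(self):
        cfg = ControllerConfig()
        state = ControllerState(last_update_t=50.0)
        with pytest.raises(ValueError, match="backwards"):
            update(state, cfg, 120.0, 124.0, 40.0)

    @settings(deadline=None, max_examples=100)
    @given(
        hrs=st.lists(st.floats(40.0, 200.0), min_size=1, max_size=60),
        kp=st.floats(0.0, 10.0),
        ki=st.floats(0.0, 1.0),
    )
    def test_command_always_within_bounds(self, hrs, kp, ki):
        cfg = ControllerConfig(kp=kp, ki=ki, p_min=0.0, p_max=250.0)
        state = ControllerState(last_command=cfg.p_min, last_update_t=0.0)
        for i, hr in enumerate(hrs):
            state, cmd = update(state, cfg, hr, 124.0, (i + 1) * 5.0)
            assert cfg.p_min <= cmd <= cfg.p_max


class TestRamp:
    def test_boundaries_and_linearity(self):
        cfg = ControllerConfig(ramp_target_power=150.0, ramp_rise=None, ramp_duration=180.0)
        assert ramp_command(cfg, 0.0) == cfg.p_min
        assert ramp_command(cfg, 90.0) == pytest.approx((cfg.p_min + 150.0) / 2)

    def test_rise_then_hold(self):
        cfg = ControllerConfig(ramp_target_power=150.0, ramp_rise=90.0, ramp_duration=180.0)
        assert ramp_command(cfg, 45.0) == pytest.approx(75.0)
        assert ramp_command(cfg, 90.0) == pytest.approx(150.0)
        assert ramp_command(cfg, 179.0) == pytest.approx(150.0)

    def test_outside_ramp_rejected(self):
        cfg = ControllerConfig(ramp_target_power=150.0)
        with pytest.raises(ValueError):
            ramp_command(cfg, 180.0)
        with pytest.raises(ValueError):
            ramp_command(cfg, -1.0)

    def test_bumpless_transfer(self):
        """With zero error at handover the first closed-loop command equals
        the ramp's final power."""
        cfg = ControllerConfig(kp=3.0, ki=0.1, ramp_target_power=150.0)
        state = handover_state(cfg, t=180.0)
        state, cmd = update(state, cfg, 124.0, 124.0, t=185.0)
        assert cmd == pytest.approx(150.0)

    def test_unresolved_ramp_power_rejected(self):
        cfg = ControllerConfig(ramp_target_power=None)
        with pytest.raises(ValueError, match="unresolved"):
            ramp_command(cfg, 10.0)
        with pytest.raises(ValueError, match="unresolved"):
            handover_state(cfg, 180.0)

    def test_rise_longer_than_ramp_rejected(self):
        with pytest.raises(ValueError):
            ControllerConfig(ramp_rise=200.0, ramp_duration=180.0)


class TestRecordRamp:
    def test_replayed_schedule_matches_original(self, reference_participant, short_profile):
        trace = run_session(
            reference_participant, None, short_profile, ControllerConfig(), rng_seed=3
        )
        schedule = record_ramp(trace)
        assert schedule.size == 180
        np.testing.assert_array_equal(schedule, trace.power_applied[:180])

    def test_trace_without_ramp_rejected(self, reference_participant, short_profile):
        trace = run_session(
            reference_participant, None, short_profile, ControllerConfig(), rng_seed=3
        )
        trace.phase[:] = "closed_loop"
        with pytest.raises(ValueError, match="ramp"):
            record_ramp(trace)


def test_determinism_identical_command_sequences(reference_participant, short_profile):
    a = run_session(reference_participant, None, short_profile, ControllerConfig(), rng_seed=11)
    b = run_session(reference_participant, None, short_profile, ControllerConfig(), rng_seed=11)
    np.testing.assert_array_equal(a.power_command, b.power_command)
    np.testing.assert_array_equal(a.hr_measured, b.hr_measured)


def test_proportional_only_leaves_offset_under_drift():
    """Without the integral term, cardiovascular drift leaves a steady-state
    error — the reason the clamp is PI, not P."""
    from hrclamp import ParticipantPhysiology

    p = ParticipantPhysiology(noise_sd=0.0, drift_rate=1.0)
    profile = make_profile("constant", target_hr=124.0, duration=3600.0)
    p_only = run_session(p, None, profile, ControllerConfig(kp=3.0, ki=0.0), rng_seed=0)
    pi = run_session(p, None, profile, ControllerConfig(kp=3.0, ki=0.1), rng_seed=0)
    final_p = abs(p_only.hr_measured[-300:] - p_only.target[-300:]).mean()
    final_pi = abs(pi.hr_measured[-300:] - pi.target[-300:]).mean()
    assert final_p > 2.0
    assert final_pi < 0.5
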