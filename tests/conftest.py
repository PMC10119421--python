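import numpy as np
import pytest

from hrclamp import (
    ControllerConfig,
    ManualPolicy,
    ParticipantPhysiology,
    make_profile,
)


@pytest.fixture
def reference_participant() -> ParticipantPhysiology:
    """The documented reference participant (noise-free variant via model_copy)."""
    return ParticipantPhysiology()


@pytest.fixture
def quiet_participant() -> ParticipantPhysiology:
    """Reference physiology with sensor noise and drift disabled."""
    return ParticipantPhysiology(noise_sd=0.0, drift_rate=0.0)


@pytest.fixture
def reference_controller() -> ControllerConfig:
    return ControllerConfig()


@pytest.fixture
def coarse_policy() -> ManualPolicy:
    """30-s epochs, 5-W steps, 3-bpm deadband, no rater variability."""
    return ManualPolicy(epoch=30.0, step=5.0, deadband=3.0, step_jitter_sd=0.0, reaction_prob=1.0)


@pytest.fixture
def constant_profile():
    return make_profile("constant", target_hr=124.0, duration=3600.0)


@pytest.fixture
def short_profile():
    return make_profile("constant", target_hr=124.0, duration=900.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
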