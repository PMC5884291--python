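import numpy as np
import pytest

from motionval import ArmModel, NoiseConfig, SkeletonSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def quiet_noise():
    """Sensor model with all noise switched off."""
    return NoiseConfig(position_sd=0.0, outlier_rate=0.0)


@pytest.fixture
def short_arm():
    """Arm model with a 0.30 m upper arm for closed-form segment checks."""
    return ArmModel(upper_arm=0.30)


@pytest.fixture
def random_sequence(rng):
    """A 40-frame sequence of random (but finite) upper-limb positions."""
    n = 40
    t = np.arange(n) / 30.0
    joints = (
        "hip_center", "shoulder_center", "shoulder_right", "elbow_right",
        "wrist_right", "hand_right",
    )
    positions = {j: rng.normal(0.0, 0.5, size=(n, 3)) + [0, 0, 2] for j in joints}
    return SkeletonSequence(t, positions)
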