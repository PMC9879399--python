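import numpy as np
import pytest

from mocapval.skeleton import COMMON_LANDMARKS, SkeletonRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_recording(rng, n_landmarks=10, n_frames=100, rate=30.0):
    landmarks = tuple(f"lm{i}" for i in range(n_landmarks))
    t = np.arange(n_frames) / rate
    pos = rng.normal(0.0, 500.0, size=(n_frames, n_landmarks, 3))
    return SkeletonRecording(
        timestamps=t, positions=pos, landmarks=landmarks, nominal_rate=rate
    )


def common_static_recording(n_frames=50, rate=30.0, offset=(0.0, 0.0, 0.0)):
    """A static, anatomically ordered 21-landmark recording."""
    from mocapval.simulate import SubjectTemplate

    t = np.arange(n_frames) / rate
    pose = SubjectTemplate().pose_array() + np.asarray(offset)
    pos = np.broadcast_to(pose, (n_frames, *pose.shape)).copy()
    return SkeletonRecording(
        timestamps=t, positions=pos, landmarks=COMMON_LANDMARKS, nominal_rate=rate
    )


@pytest.fixture
def static_common():
    return common_static_recording()
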