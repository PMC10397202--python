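import numpy as np
import pytest
from hypothesis import settings

from podscape.skeleton_io import KEYPOINT_NAMES, SkeletonTrajectory, keypoint_index

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


def make_frames(n_frames: int, positions: dict[str, tuple] | None = None) -> np.ndarray:
    """Constant frames with every keypoint at a distinct default position.

    Keypoints are laid out on a line (k, 0, 10) so direction vectors between
    named parts are non-degenerate; ``positions`` overrides individual
    keypoints with fixed (x, y, z) coordinates.
    """
    base = np.zeros((len(KEYPOINT_NAMES), 3))
    base[:, 0] = np.arange(len(KEYPOINT_NAMES), dtype=float)
    base[:, 2] = 10.0
    for name, xyz in (positions or {}).items():
        base[keypoint_index(name)] = xyz
    return np.tile(base, (n_frames, 1, 1))


@pytest.fixture
def static_trajectory() -> SkeletonTrajectory:
    return SkeletonTrajectory(frames=make_frames(50))


@pytest.fixture
def random_trajectory() -> SkeletonTrajectory:
    rng = np.random.default_rng(1234)
    frames = make_frames(200) + rng.normal(0, 2.0, size=(200, 16, 3))
    return SkeletonTrajectory(frames=frames)
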