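import numpy as np
import pytest

from gaitpose.codec import CodecConfig
from gaitpose.skeleton import KeypointSet
from gaitpose.synthetic import WalkerParams, render_frames, simulate_gait


@pytest.fixture(scope="session")
def codec_cfg():
    return CodecConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_keypoints(rng):
    """Integer-pixel keypoints well inside a 512x512 frame."""
    coords = rng.integers(40, 472, size=(8, 2)).astype(float)
    return KeypointSet(coords)


@pytest.fixture(scope="session")
def small_walker():
    """A 128x128 walker used across rendering/training tests."""
    return WalkerParams(image_size=128, seed=3)


@pytest.fixture(scope="session")
def rendered_sequence(small_walker):
    traj = simulate_gait(small_walker, n_frames=20)
    frames, depths, kps = render_frames(traj, small_walker)
    return traj, frames, depths, kps
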