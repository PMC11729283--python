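import numpy as np
import pytest

from endovitals.io_core import Frame, VideoSequence
from endovitals.roi import CircleROI
from endovitals.synthetic import (DRSForwardParams, VideoScene,
                                  hemoglobin_table)


@pytest.fixture(scope="session")
def chromophores():
    return hemoglobin_table()


@pytest.fixture(scope="session")
def grid_1nm():
    return np.arange(450.0, 1001.0, 1.0)


@pytest.fixture
def forward_params():
    return DRSForwardParams()


@pytest.fixture
def quiet_scene():
    """A scene with every stochastic / modulated ingredient switched off."""
    return VideoScene(a_c=0.0, a_r=0.0, a_b=0.0, jitter_sd=0.0,
                      incursion_prob=0.0, noise_sd=0.0)


def make_uniform_video(rgb, n_frames=8, size=32, fps=40.0):
    """A video of identical frames with one constant colour."""
    pixels = np.tile(np.asarray(rgb, dtype=np.float32), (size, size, 1))
    frames = [Frame(pixels.copy(), index=i, time_s=i / fps)
              for i in range(n_frames)]
    return VideoSequence(frames=frames, fps=fps)


def full_circles(video, r=12.0):
    """One centred valid circle per frame."""
    h, w = video.shape
    return [CircleROI(cx=w / 2, cy=h / 2, r=r, residual=0.0, valid=True)
            for _ in video.frames]
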