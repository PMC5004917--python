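import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from pupiltrack import GainCalibration, LoopConfig, SceneParams


@pytest.fixture
def scene():
    """Default camera scene: 320x256 px, 42 um/px, dark pupil on bright iris."""
    return SceneParams()


@pytest.fixture
def quiet_scene():
    """Noise-free default scene for geometry-exact checks."""
    return SceneParams(noise_sigma=0.0)


@pytest.fixture
def small_scene():
    """Reduced frame for fast loop simulations in optimization tests."""
    return SceneParams(frame_width=96, frame_height=80, pupil_radius=0.6,
                       noise_sigma=3.0)


@pytest.fixture
def calibration():
    return GainCalibration()


@pytest.fixture
def loop():
    """500 Hz camera, 4 ms loop latency, +/-2.5 mm tracking range."""
    return LoopConfig()
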