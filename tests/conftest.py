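import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pulsecam import BBox, FrameSequence
from pulsecam.synth import SynthSpec, synth_video

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def skin_patch_frame():
    """100x100 frame: blue background, 40x40 skin-colored patch at center.

    Returns (frame, patch_box ground truth).
    """
    frame = np.zeros((100, 100, 3), dtype=np.uint8)
    frame[:, :] = (50, 80, 200)
    box = BBox(30, 30, 40, 40)
    frame[box.y : box.y + box.h, box.x : box.x + box.w] = (208, 150, 136)
    return frame, box


@pytest.fixture(scope="session")
def clean_video():
    """Noise-free-ish synthetic recording at 75 BPM, 30 s @ 30 fps."""
    spec = SynthSpec(hr_bpm=75.0, hr_amp=2.0, noise_sd=1.0, seed=7)
    seq, truth = synth_video(spec)
    return seq, truth


@pytest.fixture
def short_sequence():
    frames = np.zeros((90, 20, 20, 3), dtype=np.uint8)
    return FrameSequence(frames=frames, fps=30.0)
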