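import numpy as np
import pytest

from fadyn.dynamics import AnalysisConfig, compute_maps
from fadyn.synthetic import SceneConfig, render_video


@pytest.fixture(scope="session")
def noiseless_retina():
    """Noiseless, motion-free 16-bit retina scene plus its dynamics maps."""
    cfg = SceneConfig(seed=11, noise_sigma=0.0, noise_gain=0.0, bit_depth=16)
    stack, truth = render_video(cfg)
    maps = compute_maps(stack, AnalysisConfig(), label_map=truth.label_map)
    return cfg, stack, truth, maps


@pytest.fixture(scope="session")
def noisy_motion_retina():
    """Retina scene with 3 px smooth drift and camera noise (registration fixture)."""
    cfg = SceneConfig(seed=3, motion_amplitude_px=3.0, noise_sigma=2.0, noise_gain=0.01)
    stack, truth = render_video(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def tiny_scene():
    """Small, short recording for I/O and CLI smoke tests."""
    cfg = SceneConfig(shape=(32, 32), duration_s=22.0, seed=7)
    stack, truth = render_video(cfg)
    return cfg, stack, truth


def sample_times(frame_rate: float = 30.0, duration: float = 60.0, onset: float = 5.0):
    return np.arange(int(round(duration * frame_rate))) / frame_rate - onset
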