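import numpy as np
import pytest

from whistlekit.audio import AudioClip
from whistlekit.synthetic import (
    NoiseProfile,
    SceneSpec,
    WhistleEventSpec,
    render_scene,
)

FS = 96000.0


@pytest.fixture(scope="session")
def tone_clip():
    """2 s pure 10 kHz tone at 96 kHz, amplitude 0.5."""
    t = np.arange(int(2 * FS)) / FS
    return AudioClip(0.5 * np.sin(2 * np.pi * 10000 * t), FS, source_id="tone10k")


@pytest.fixture(scope="session")
def demo_scene():
    """One 2 s scene with a single 20 dB whistle at [0.5, 1.0] s."""
    event = WhistleEventSpec(
        t_start=0.5, duration=0.5, f_start=8000.0, f_end=12000.0, snr_db=20.0
    )
    spec = SceneSpec(duration_s=2.0, events=(event,), noise=NoiseProfile(), seed=7)
    clip, anns = render_scene(spec)
    return spec, clip, anns


@pytest.fixture(scope="session")
def tiny_image_task():
    """Trivially separable image set: bright square present vs absent."""
    rng = np.random.default_rng(5)
    n = 120
    x = (rng.random((n, 32, 32, 1)) * 0.3).astype(np.float32)
    y = rng.integers(0, 2, n)
    for i in range(n):
        if y[i]:
            x[i, 8:22, 8:22, 0] += 0.7
    return x, y
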