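import numpy as np
import pytest

import flickermap as fm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_stack(frames, frame_rate=1000.0, pixel_pitch=108.3, **kw):
    return fm.ImageStack(
        frames=np.asarray(frames), frame_rate=frame_rate, pixel_pitch=pixel_pitch, **kw
    )


@pytest.fixture
def quiet_camera():
    """Noise-free camera for analytic checks."""
    return fm.CameraModel(shot_noise=False, read_noise_sd=0.0)


@pytest.fixture
def quiet_bundle():
    """Deterministic sinusoidal bundle with all noise terms off."""
    return fm.BundleModel(
        waveform="sinusoid", dwell_noise_cv=0.0, position_noise_sd=0.0
    )
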