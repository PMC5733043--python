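import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import oisi

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bands():
    return oisi.default_bands()


@pytest.fixture(scope="session")
def clean_scene():
    """Small noiseless, fluctuation-free scene: blob well inside the border ring."""
    return oisi.SceneParams(
        height=80,
        width=100,
        blob_center=(40, 50),
        blob_sigma=5.0,
        noise_sigma=0.0,
        illumination_fluctuation_amp=0.0,
        n_trials=1,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_protocol():
    """Short protocol for fast unit tests: 4 s trial at 5 Hz (20 frames)."""
    return oisi.Protocol(baseline_s=1.0, stim_s=1.0, recovery_s=2.0, frame_rate_hz=5.0)


def constant_stack(value, protocol, shape=(12, 16), band="RED"):
    data = np.full((protocol.n_frames, *shape), float(value))
    return oisi.FrameStack(data=data, band=band, protocol=protocol)
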