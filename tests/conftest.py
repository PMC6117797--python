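import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lungtwin import BreathingSpec, CameraConfig, GeometryConfig, MotorSpec

# the fixtures drawn inside @given are frozen dataclasses, safe to reuse
settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def geometry():
    """Mid-size loop: width 20 mm, height 20 mm."""
    return GeometryConfig(r=10.0, d1=10.0, d2=20.0, l=20.0)


@pytest.fixture
def breathing():
    """16 breaths/min: one breath every 3.75 s."""
    return BreathingSpec(period_s=3.75)


@pytest.fixture
def motor():
    return MotorSpec()


@pytest.fixture
def small_camera():
    """Low-resolution camera for fast render/track tests."""
    return CameraConfig(
        width_px=160, height_px=120, px_per_mm=4.0, fps=10.0,
        sticker_radius_mm=1.5, noise_sigma=0.0, seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
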