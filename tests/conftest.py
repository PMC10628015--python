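import numpy as np
import pytest

from ablashape.profiles import AblationProfile, DeviceModel, ProfileSegment
from ablashape.width_model import DEFAULT_COEFFS, CalibrationCoefficients


@pytest.fixture
def device():
    return DeviceModel()


@pytest.fixture
def coeffs():
    """Realistic planning coefficients (20 mm width at 100 W / 0.1 mm/s)."""
    return DEFAULT_COEFFS


@pytest.fixture
def recovery_truth():
    """Canonical simulation truth for parameter-recovery checks."""
    return CalibrationCoefficients(
        alpha=30.0, beta_power=8.0, beta_velocity=-6.0,
        eps=0.2, eps_power=0.02, eps_velocity=0.5,
    )


@pytest.fixture
def simple_profile():
    """One 35 mm pass at 100 W / 0.1 mm/s (350 s, 35 kJ)."""
    return AblationProfile(
        [ProfileSegment(x_start=0.0, x_end=35.0, power=100.0, velocity=0.1)]
    )


@pytest.fixture
def mixed_profile():
    """Dwell + pass + pause + pass, exercising every segment kind."""
    return AblationProfile(
        [
            ProfileSegment(0.0, 0.0, 100.0, 0.0, dwell_time=60.0),
            ProfileSegment(0.0, 12.0, 100.0, 0.1),
            ProfileSegment(12.0, 12.0, 0.0, 0.0, dwell_time=30.0),
            ProfileSegment(12.0, 30.0, 60.0, 0.2),
        ]
    )


def make_rng_profile(rng, n_segments=5):
    """Random well-formed profile for property tests."""
    segs = []
    x = 0.0
    for _ in range(n_segments):
        kind = rng.integers(0, 3)
        power = float(rng.choice([0.0, 60.0, 80.0, 100.0, 120.0, 140.0]))
        if kind == 0:  # dwell
            segs.append(ProfileSegment(x, x, power, 0.0, dwell_time=float(rng.uniform(5, 120))))
        else:
            dx = float(rng.uniform(1.0, 15.0))
            v = float(rng.uniform(0.02, 0.5))
            segs.append(ProfileSegment(x, x + dx, power, v))
            x += dx
    return AblationProfile(segs)
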