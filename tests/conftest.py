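import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrtilt.phantom import PhantomSpec, make_phantom
from mrtilt.volio import TiltAngles
from mrtilt.yaw import select_elliptical_slices

settings.register_profile(
    "suite",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def untilted():
    """Default noiseless phantom with zero tilt, shared across the suite."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def untilted_volume(untilted):
    return untilted[0]


@pytest.fixture(scope="session")
def untilted_truth(untilted):
    return untilted[1]


@pytest.fixture(scope="session")
def untilted_selection(untilted_volume):
    return select_elliptical_slices(untilted_volume)


@pytest.fixture(scope="session")
def faceless():
    """Phantom without nasal anatomy (no notch, no nose, no distractors)."""
    spec = PhantomSpec(notch_depth_mm=0.0, nose_height_mm=0.0,
                       include_distractors=False)
    return make_phantom(spec)


def tilted_phantom(pitch=0.0, yaw=0.0, roll=0.0, **kwargs):
    spec = PhantomSpec(applied_tilt=TiltAngles(pitch, yaw, roll), **kwargs)
    return make_phantom(spec)
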