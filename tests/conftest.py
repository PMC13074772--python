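import numpy as np
import pytest

from spinecm import AngularTrace, NormalizedProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_trace():
    """800-sample ramp: angle(j) = j/10 at 100 Hz."""
    t = np.arange(800) / 100.0
    return AngularTrace(t=t, angle=np.arange(800) / 10.0, plane="transverse", posture="adams")


@pytest.fixture
def random_profile(rng):
    """Fixed pseudo-random 400-point profile, values on a dyadic grid so an
    exact rational least-squares oracle can reproduce them."""
    vals = np.round(rng.normal(0.0, 5.0, 400) * 2**20) / 2**20
    return NormalizedProfile(values=vals, plane="sagittal", posture="standing")
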