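import numpy as np
import pytest

from incise import ArchetypeSpec, ForceProfile, MaxwellParams, VelocityProfile


@pytest.fixture
def maxwell():
    """Study-default Maxwell body: E = 1 N/cm, eta = 0.5 N s/cm, 30 Hz."""
    return MaxwellParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def step_archetype():
    """A two-regime archetype with well-separated velocity levels."""
    return ArchetypeSpec(
        name="fixture",
        v_L=1.0,
        v_U=6.0,
        q12=0.05,
        q21=0.05,
        sigma_L=0.35,
        sigma_U=0.35,
        seed=7,
    )


@pytest.fixture
def random_profile(rng):
    samples = np.abs(rng.normal(0.4, 0.1, 120)) + 0.01
    return ForceProfile(samples=samples, rate=30.0)


def constant_velocity(value: float, n: int = 120, rate: float = 30.0) -> VelocityProfile:
    return VelocityProfile(samples=np.full(n, value), rate=rate)
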