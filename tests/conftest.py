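import numpy as np
import pytest

from aequosim import AequorinPool, DetectorConfig, EmissionProfile, QdcConfig


@pytest.fixture
def det() -> DetectorConfig:
    return DetectorConfig()


@pytest.fixture
def qdc() -> QdcConfig:
    return QdcConfig()


@pytest.fixture
def const_profile():
    """Factory for a constant-rate emission profile.

    The pool ramps down linearly so that the exact per-bin emission equals
    rate * dt, keeping the profile invariants satisfied.
    """

    def make(rate: float, duration: float, dt: float) -> EmissionProfile:
        n = int(round(duration / dt))
        t = np.arange(n + 1) * dt
        pool = rate * (duration - t)
        return EmissionProfile(t=t, rate=np.full(n + 1, float(rate)), pool=pool,
                               provenance=f"constant {rate:g} Hz")

    return make


@pytest.fixture
def unit_pool() -> AequorinPool:
    return AequorinPool(1.0)
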