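import numpy as np
import pytest

from weibull_release import (
    PRESETS,
    ReleaseProfile,
    WeibullParams,
    weibull_cdf,
)


@pytest.fixture
def nanofibers() -> WeibullParams:
    return PRESETS["nanofibers"]


@pytest.fixture
def colloids() -> WeibullParams:
    return PRESETS["colloids"]


@pytest.fixture
def non_irradiated() -> WeibullParams:
    return PRESETS["non_irradiated"]


def make_noiseless_profile(p: WeibullParams, times=None, **kwargs) -> ReleaseProfile:
    """Exact Weibull CDF values on a default log grid (independent inputs)."""
    if times is None:
        times = np.geomspace(0.25, 80.0, 25)
    times = np.asarray(times, dtype=float)
    return ReleaseProfile(
        times=times, release=weibull_cdf(times, p), m_inf_hint=p.m_inf, **kwargs
    )


@pytest.fixture
def noiseless_colloids(colloids) -> ReleaseProfile:
    return make_noiseless_profile(colloids)


@pytest.fixture
def noiseless_nanofibers(nanofibers) -> ReleaseProfile:
    return make_noiseless_profile(nanofibers)
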