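import numpy as np
import pytest
from hypothesis import settings

from aocarbon.forcing import AtmosphereCurve
from aocarbon.pipeline import normalize_profiles
from aocarbon.synthetic import SyntheticSpec, generate_dataset, make_atmosphere

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constant_curve():
    """Flat atmosphere at F14C = 1 from deep time to 2020."""
    years = np.arange(-53000, 2021)
    return AtmosphereCurve("synthetic", years, np.ones(years.size))


@pytest.fixture(scope="session")
def bomb_curve():
    """Synthetic forcing with a 1964 bomb peak at 1.8 fraction modern."""
    return make_atmosphere(SyntheticSpec())


@pytest.fixture(scope="session")
def noisefree_dataset():
    """50 noise-free profiles, single active end-member, flat atmosphere.

    In this regime the binary mixing model is exactly specified and
    normalization to 2000 is the identity, so fits must recover the true
    aOC to numerical precision.
    """
    spec = SyntheticSpec(
        seed=11, n_profiles=50, noise_sd_f14c=0.0,
        turnover_surface_yr=200.0, turnover_deep_yr=200.0,
        atm_peak_f14c=1.0,
    )
    profiles, truths, curve = generate_dataset(spec)
    normalize_profiles(profiles, curve)
    return profiles, truths, curve


@pytest.fixture(scope="session")
def noisy_dataset():
    """200 profiles with 0.02 fraction-modern noise under the bomb forcing."""
    spec = SyntheticSpec(
        seed=23, n_profiles=200, noise_sd_f14c=0.02,
        turnover_surface_yr=200.0, turnover_deep_yr=200.0,
    )
    profiles, truths, curve = generate_dataset(spec)
    normalize_profiles(profiles, curve)
    return profiles, truths, curve
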