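"""Shared fixtures: small phantoms generated once per session."""

import numpy as np
import pytest
from hypothesis import settings

from pibgm import PhantomSpec, make_phantom

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

ZERO_SDS = {"fat": 0.0, "muscle": 0.0, "marrow": 0.0, "cortex": 0.0}
NOISY_SDS = {"fat": 20.0, "muscle": 20.0, "marrow": 20.0, "cortex": 20.0}


def noiseless_spec(**overrides) -> PhantomSpec:
    kwargs = dict(tissue_sds=dict(ZERO_SDS), pet_noise_sd=0.0, seed=1)
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def clean_case():
    """Noiseless default phantom (bed on)."""
    return make_phantom(noiseless_spec())


@pytest.fixture(scope="session")
def noisy_case():
    """Phantom with HU noise sd 20 in every tissue and mild PET noise."""
    return make_phantom(PhantomSpec(tissue_sds=dict(NOISY_SDS),
                                    pet_noise_sd=0.05, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
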