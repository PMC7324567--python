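import math

import numpy as np
import pytest

import cardioqsm as cq


@pytest.fixture(scope="session")
def small_spec():
    """Noiseless ex vivo-profile phantom on a 48³ grid (desk-scale)."""
    return cq.default_spec(48, snr=math.inf, seed=3)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return cq.build_phantom(small_spec)


@pytest.fixture(scope="session")
def small_series(small_spec, small_truth):
    return cq.synthesize_echoes(small_truth, small_spec)


@pytest.fixture(scope="session")
def noisy_spec():
    """Same phantom at the study's SNR 40, fixed seed."""
    return cq.default_spec(48, snr=40.0, seed=7)


@pytest.fixture(scope="session")
def noisy_truth(noisy_spec):
    return cq.build_phantom(noisy_spec)


@pytest.fixture(scope="session")
def noisy_series(noisy_spec, noisy_truth):
    return cq.synthesize_echoes(noisy_truth, noisy_spec)


@pytest.fixture(scope="session")
def noisy_mask(noisy_series):
    return cq.make_mask(noisy_series)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
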