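"""Shared fixtures: small deterministic phantoms, coils, and sampled data."""

import numpy as np
import pytest

import gsvs


@pytest.fixture(scope="session")
def small_spec():
    return gsvs.default_spec(grid_shape=(16, 16, 8))


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return gsvs.make_phantom(small_spec)


@pytest.fixture(scope="session")
def small_coils(small_spec):
    return gsvs.make_coils(small_spec.grid_shape, n_coils=4, seed=1)


@pytest.fixture(scope="session")
def unit_coil(small_spec):
    return gsvs.make_coils(small_spec.grid_shape, n_coils=1, uniform=True)


@pytest.fixture(scope="session")
def whitened_coils(small_coils):
    return gsvs.whiten_coils(small_coils)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def complex_noise(rng, shape, sigma=1.0):
    """Circularly symmetric complex Gaussian, variance sigma^2 per entry."""
    return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) * (
        sigma / np.sqrt(2.0)
    )
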