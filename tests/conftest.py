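"""Shared fixtures: small geometries and forward models built once."""

import numpy as np
import pytest

import cohdics as cd


@pytest.fixture(scope="session")
def sensors_small():
    return cd.make_spherical_sensor_array(32, 0.10, 0.85)


@pytest.fixture(scope="session")
def grid_small():
    return cd.make_spherical_source_grid(60, 0.07)


@pytest.fixture(scope="session")
def fwd_small(grid_small, sensors_small):
    return cd.compute_forward(grid_small, sensors_small)


@pytest.fixture(scope="session")
def fwd_tan_small(fwd_small):
    return cd.forward_to_tangential(fwd_small)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_hermitian_psd(rng, n, rank=None):
    """Random Hermitian positive semidefinite matrix (helper for tests)."""
    rank = rank or n
    a = rng.standard_normal((n, rank)) + 1j * rng.standard_normal((n, rank))
    return a @ a.conj().T / rank
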