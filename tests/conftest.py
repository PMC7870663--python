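"""Shared fixtures: coarse phantoms keep the suite fast; the acceptance
tests build their own full-resolution data."""

import numpy as np
import pytest

from innerear.phantom import (
    NOISE_SIGMA_SNR4,
    PhantomParams,
    generate_phantom,
    make_truth,
    phantom_region_masks,
)

COARSE = dict(spacing=0.4, extent_mm=(36.0, 36.0, 28.0))


@pytest.fixture(scope="session")
def coarse_params():
    return PhantomParams(noise_sigma=NOISE_SIGMA_SNR4, **COARSE)


@pytest.fixture(scope="session")
def coarse_noiseless_params():
    return PhantomParams(noise_sigma=0.0, **COARSE)


@pytest.fixture(scope="session")
def coarse_phantom(coarse_params):
    channels, truth = generate_phantom(
        coarse_params, seed=11, channels=("t2like",), truth_volumes=False)
    return channels, truth


@pytest.fixture(scope="session")
def coarse_noiseless(coarse_noiseless_params):
    channels, truth = generate_phantom(
        coarse_noiseless_params, seed=0, channels=("t2like",),
        truth_volumes=False)
    return channels, truth


@pytest.fixture(scope="session")
def default_truth():
    """Ground truth of the default-parameter phantom (no rendering)."""
    return make_truth(PhantomParams(), meshes=True, volumes=True)


@pytest.fixture(scope="session")
def coarse_labyrinth_mask(coarse_params):
    return phantom_region_masks(coarse_params, regions=("labyrinth",))["labyrinth"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
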