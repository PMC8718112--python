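"""Shared fixtures: small phantoms kept fast, full-size ones session-scoped."""

import numpy as np
import pytest

from receptorquant.synthetic import CellPhantomParams, make_cell_stack


@pytest.fixture(scope="session")
def sharp_phantom():
    """Full-size noise-free, blur-free phantom with its truth record."""
    params = CellPhantomParams(noise_sd=0.0, psf_sigma_px=0.0, rng_seed=11)
    return make_cell_stack(params)


@pytest.fixture(scope="session")
def small_phantom_params():
    """Small, fast phantom parameters reused across tests."""
    return dict(
        image_size=96,
        radius_px=30.0,
        erosion_px=8,
        puncta_count=4,
        puncta_radius_px=2,
        noise_sd=0.0,
        psf_sigma_px=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
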