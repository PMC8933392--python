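import numpy as np
import pytest

from histogate import IhcSimParams, simulate_ihc_image


@pytest.fixture(scope="session")
def clean_field():
    """A noise-free synthetic field with well-separated nuclei (exact oracle)."""
    params = IhcSimParams(
        n_cells=60,
        true_positive_fraction=0.4,
        background_noise_sd=0.0,
        seed=42,
    )
    image, truth = simulate_ihc_image(params)
    return params, image, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
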