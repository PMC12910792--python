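import numpy as np
import pytest

import specklepipe as sp


@pytest.fixture(scope="session")
def clean_field():
    """Noise-free sparse field with well-separated nuclei and its truth."""
    spec = sp.sparse_preset(
        field_size_px=(512, 512),
        seed=42,
        noise_gain=0.0,
        read_noise_sd=0.0,
        nucleus_density=8.0,
        condensates_per_nucleus_mean=4.0,
    )
    plane, truth = sp.generate_plane(spec)
    return spec, plane, truth


@pytest.fixture(scope="session")
def noisy_field():
    """Field at the default noise level (shot + read noise)."""
    spec = sp.sparse_preset(field_size_px=(512, 512), seed=43)
    plane, truth = sp.generate_plane(spec)
    return spec, plane, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
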