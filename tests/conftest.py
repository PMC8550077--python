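import numpy as np
import pytest

from ppaseg.synth import SynthParams, generate_sample


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def tiny_params():
    """Desk-scale generator settings (64 px canvas)."""
    return SynthParams(canvas_size=64, disc_radius_range=(8.0, 12.0),
                       ppa_width_fraction_range=(0.15, 0.7),
                       vessel_count=3)


@pytest.fixture(scope="session")
def tiny_sample(tiny_params):
    return generate_sample(tiny_params, seed=7)


@pytest.fixture(scope="session")
def tiny_channels():
    """CPU-friendly pyramid widths for full-network tests."""
    return (8, 8, 16, 24, 32)
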