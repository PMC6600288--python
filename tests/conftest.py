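import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("deterministic")

from bosspls.synthetic import (
    AdulterationDesign,
    ArtifactModel,
    GaussianBand,
    OilSpectrumModel,
    default_grid,
    default_oil_models,
    generate_dataset,
    make_grid,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grid():
    """A coarse 120-point version of the instrument grid."""
    return make_grid(9999.10, 3999.64, 120)


@pytest.fixture(scope="session")
def noise_free_dataset(small_grid):
    """Default design on a coarse grid with every artifact switched off."""
    evoo, adulterants = default_oil_models()
    return generate_dataset(
        AdulterationDesign(),
        evoo,
        adulterants,
        small_grid,
        ArtifactModel(),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_oil_models():
    """Two-band oils on a short grid for hand-checkable spectra."""
    evoo = OilSpectrumModel(
        "evoo", (GaussianBand(80.0, 5.0, 1.0), GaussianBand(40.0, 5.0, 0.5))
    )
    adulterant = OilSpectrumModel(
        "other", (GaussianBand(80.0, 5.0, 0.2), GaussianBand(60.0, 5.0, 0.8))
    )
    return evoo, adulterant
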