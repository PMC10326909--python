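import numpy as np
import pytest

from sfcquant import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded draw of the default synthetic dataset (127 chemicals)."""
    return generate_dataset(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small noiseless dataset: RF estimation must be exact."""
    return generate_dataset(
        SynthConfig(
            n_chemicals=12,
            n_descriptors=30,
            n_informative=3,
            sigma_instrument=0.0,
            sigma_area=0.0,
            saturation_quantile=1.0,
            seed=3,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
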