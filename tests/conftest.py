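import numpy as np
import pytest

from rectomics import CohortConfig, digital_phantom, generate_cohort


@pytest.fixture(scope="session")
def phantom():
    return digital_phantom()


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny 2-channel cohort shared by I/O and pipeline tests."""
    config = CohortConfig(
        n_patients=6,
        volume_shape=(16, 16, 16),
        tumor_radius_range_mm=(5.0, 6.0),
        channels=("T1w", "L2"),
        seed=11,
    )
    return config, generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
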