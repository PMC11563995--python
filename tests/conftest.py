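import numpy as np
import pytest

from perfterr.phantom import (
    CohortConfig,
    ExperimentAssignment,
    PhantomConfig,
    TerritoryTruth,
    build_specimen_phantom,
    region_masks,
)

#: Small grid used throughout the tests; large enough that every region and
#: both halves are nonempty, small enough for sub-second specimen builds.
SMALL_GRID = (24, 16, 32)


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    return PhantomConfig(grid_shape=SMALL_GRID)


@pytest.fixture(scope="session")
def noise_free_config() -> PhantomConfig:
    return PhantomConfig(grid_shape=SMALL_GRID, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_masks(small_config):
    return region_masks(small_config)


@pytest.fixture(scope="session")
def small_cohort_config(small_config) -> CohortConfig:
    return CohortConfig(phantom=small_config)


@pytest.fixture()
def noise_free_specimen(noise_free_config):
    """Noise-free specimen with uniform MFCA fraction 0.7, MFCA infused."""
    truth = TerritoryTruth.uniform(0.7)
    return build_specimen_phantom(
        noise_free_config,
        truth,
        ExperimentAssignment("left", "MFCA"),
        seed=11,
        specimen_id="NF1",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
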