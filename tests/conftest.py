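import numpy as np
import pytest

from fibrodens import PhantomConfig, StageParams, generate_lung_geometry


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """A small thorax grid for fast structural tests."""
    return PhantomConfig(grid_shape=(64, 48, 48), spacing_mm=(0.25, 0.25, 0.25),
                         stage=StageParams(week=0, consolidation_fraction=0.0),
                         rng_seed=123)


@pytest.fixture(scope="session")
def small_geometry(small_config):
    return generate_lung_geometry(small_config)


@pytest.fixture(scope="session")
def default_geometry():
    """The full-size default thorax (both lungs ~1e5 voxels each)."""
    return generate_lung_geometry(PhantomConfig(rng_seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
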