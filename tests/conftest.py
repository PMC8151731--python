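import numpy as np
import pytest

from pressurepose.features import FeatureExtractor
from pressurepose.pipeline import benchmark_layouts, extract_feature_table
from pressurepose.pressuremap import MatGeometry, PressureFrame, default_segmentation
from pressurepose.synth import ScenarioSpec, generate_dataset


@pytest.fixture(scope="session")
def backrest_geometry():
    return MatGeometry.backrest()


@pytest.fixture(scope="session")
def seatpan_geometry():
    return MatGeometry.seatpan()


@pytest.fixture(scope="session")
def backrest_scheme(backrest_geometry):
    return default_segmentation(backrest_geometry)


@pytest.fixture(scope="session")
def seatpan_scheme(seatpan_geometry):
    return default_segmentation(seatpan_geometry)


@pytest.fixture(scope="session")
def extractor():
    return FeatureExtractor()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_frame(geometry, rng, density=1.0):
    values = rng.random(geometry.shape)
    if density < 1.0:
        values *= rng.random(geometry.shape) < density
    return PressureFrame(geometry, values)


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale scenario for pipeline-level tests."""
    return generate_dataset(ScenarioSpec(n_subjects=4, n_tasks=6, n_frames=40, seed=7))


@pytest.fixture(scope="session")
def small_feature_table(small_dataset):
    return extract_feature_table(small_dataset)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study scenario: 10 subjects x 10 tasks x 60 frames."""
    return generate_dataset(ScenarioSpec(seed=1))


@pytest.fixture(scope="session")
def default_benchmark(default_dataset):
    """Full-resolution vs level-5 layout LOSO benchmark on the default scenario."""
    return benchmark_layouts(default_dataset, [5], seed=0)
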