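import numpy as np
import pytest
from hypothesis import settings

import spectrabench as sb

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grid() -> sb.WavelengthGrid:
    """A coarse 60-point grid keeping synthetic-data tests cheap."""
    return sb.make_wavelength_grid(350.14, 649.98, 60)


@pytest.fixture(scope="session")
def ground_truth(small_grid) -> sb.GroundTruthModel:
    config = sb.GroundTruthConfig(grid=small_grid)
    return sb.generate_ground_truth(config, seed=7)


@pytest.fixture(scope="session")
def small_design() -> sb.RawDesign:
    """3 animals x 8 tissues x 2 spots x 4 repetitions."""
    return sb.RawDesign(n_animals=3, n_spots=2, n_repetitions=4)


@pytest.fixture(scope="session")
def raw_table(ground_truth, small_design):
    return sb.generate_raw_dataset(ground_truth, small_design, seed=11)


@pytest.fixture(scope="session")
def preprocessed(raw_table):
    return sb.average_spectra(raw_table)


@pytest.fixture(scope="session")
def full_raw_table(ground_truth):
    """The full 12 x 8 x 6 x 30 design on the coarse grid."""
    return sb.generate_raw_dataset(ground_truth, sb.RawDesign(), seed=11)


@pytest.fixture(scope="session")
def full_preprocessed(full_raw_table):
    return sb.average_spectra(full_raw_table)


@pytest.fixture(scope="session")
def class_estimates(full_preprocessed):
    return sb.estimate_class_params(full_preprocessed)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
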