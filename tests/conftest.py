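import numpy as np
import pytest

from sferlab.config import GeneratorConfig
from sferlab.cohort import generate_state_sequences
from sferlab.sequences import prepare_sequences


@pytest.fixture(scope="session")
def hazard_cohort():
    """Calibrated hazard-mode cohort used across hazard/model tests."""
    cfg = GeneratorConfig(seed=101)
    return generate_state_sequences(cfg, 5000, mode="hazard")


@pytest.fixture(scope="session")
def hazard_sequences(hazard_cohort):
    return prepare_sequences(hazard_cohort.activity)


@pytest.fixture(scope="session")
def sfer_cohort():
    cfg = GeneratorConfig(seed=202)
    return generate_state_sequences(cfg, 4000, mode="sfer")


@pytest.fixture(scope="session")
def sfer_sequences(sfer_cohort):
    return prepare_sequences(sfer_cohort.activity)


@pytest.fixture(scope="session")
def small_scene():
    from sferlab.spatial import synthetic_scene
    return synthetic_scene(n_cells=8, n_frames=9600, n_bins=24,
                           rng=np.random.default_rng(7))
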