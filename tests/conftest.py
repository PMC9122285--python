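import numpy as np
import pytest

import convsdm
from convsdm.pipeline import run_experiment

# the fixed seed of the default desk-scale study reproduced by the test suite
STUDY_SEED = 1


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic study system: 2 x 2 km at 2 m/px, 20 species
    (8 context species), 4,500 occurrences, 32 x 32 px patches."""
    return convsdm.generate_world(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def experiment(default_world):
    """Full end-to-end run: spatial split, CNN training, baseline, metrics."""
    return run_experiment(default_world, seed=STUDY_SEED, k=5)


@pytest.fixture(scope="session")
def tiny_world():
    """A small, fast world for integration-style unit tests."""
    return convsdm.generate_world(
        extent=400.0,
        resolution=2.0,
        n_species=6,
        n_context=2,
        n_occurrences=500,
        patch_px=16,
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
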