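import numpy as np
import pytest

import atroprop as ap


@pytest.fixture(scope="session")
def geometry():
    return ap.make_geometry(60, rng_seed=1)


@pytest.fixture(scope="session")
def distances(geometry):
    return ap.distance_matrix(geometry)


@pytest.fixture(scope="session")
def connectome(geometry):
    return ap.make_connectome(geometry, target_density=0.15, decay_mm=30.0, rng_seed=2)


@pytest.fixture(scope="session")
def small_cohort():
    """Small but complete synthetic cohort shared across test modules."""
    cfg = ap.SimulationConfig(
        R=40, n_per_group=40, visits=3, n_connectome_subjects=5, rng_seed=7
    )
    return ap.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def smooth_map(distances):
    rng = np.random.default_rng(11)
    return ap.smooth_field(distances, 20.0, rng)[0]
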