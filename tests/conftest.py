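import numpy as np
import pytest

from tractoica import (
    average_matrices,
    make_geometry,
    plant_components,
    simulate_subject_matrix,
)


@pytest.fixture(scope="session")
def geometry():
    """Standard two-hemisphere phantom: 2 x 100 seeds, 20x16x16 volume."""
    return make_geometry(100, (20, 16, 16), seed=1)


@pytest.fixture(scope="session")
def truth(geometry):
    """8 mirror-symmetric planted components with disjoint supports."""
    return plant_components(geometry, k_true=8, overlap=0.0, symmetric=True, seed=2)


@pytest.fixture(scope="session")
def group_matrix(geometry, truth):
    """Group average of 10 simulated subjects, 10,000 streamlines/seed."""
    subjects = [
        simulate_subject_matrix(truth, geometry, seed=100 + i, subject_id=f"sub-{i}")
        for i in range(10)
    ]
    return average_matrices(subjects)


@pytest.fixture(scope="session")
def tiny_geometry():
    """Smallest practical phantom for cheap IO and property tests."""
    return make_geometry(8, (4, 4, 4), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
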