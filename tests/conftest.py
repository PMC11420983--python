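import numpy as np
import pytest

from clsmverse.core_io import VolumeGrid
from clsmverse.synthetic_cohort import CohortSpec, make_cohort


@pytest.fixture
def unit_grid():
    """20^3 grid with 1 mm isotropic voxels, origin at the corner voxel centre."""
    return VolumeGrid(np.zeros((20, 20, 20)), np.eye(4))


@pytest.fixture
def aniso_grid():
    """Anisotropic grid matching a clinical DWI protocol (1.9 x 1.9 x 2.38 mm)."""
    aff = np.diag([1.9, 1.9, 2.38, 1.0])
    aff[:3, 3] = [-19.0, -19.0, -23.8]
    return VolumeGrid(np.zeros((20, 20, 20)), aff)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant cohort shared by pipeline-level tests."""
    return make_cohort(CohortSpec(seed=7, n_participants=12))
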