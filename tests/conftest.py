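import numpy as np
import pytest

import cstract as cs
from cstract.pipeline import run_tracts, species_tracking_params


@pytest.fixture(scope="session")
def human_phantom():
    return cs.build_phantom(cs.default_spec("human", rng_seed=0))


@pytest.fixture(scope="session")
def macaque_phantom():
    return cs.build_phantom(cs.default_spec("macaque", rng_seed=1))


@pytest.fixture(scope="session")
def human_library(human_phantom):
    return cs.load_library(human_phantom.atlas, human_phantom.masks,
                           fld=human_phantom.field, species="human")


@pytest.fixture(scope="session")
def human_tracts(human_phantom):
    """Left-hemisphere tract distributions on the shipped phantom (one seed)."""
    params = species_tracking_params(human_phantom, 1, seeds_per_voxel=40)
    tracts, classes = run_tracts(human_phantom, params)
    return tracts, classes, params


@pytest.fixture(scope="session")
def macaque_tracts(macaque_phantom):
    params = species_tracking_params(macaque_phantom, 1, seeds_per_voxel=40)
    tracts, classes = run_tracts(macaque_phantom, params)
    return tracts, classes, params


@pytest.fixture(scope="session")
def mini_base():
    return cs.build_phantom(cs.mini_cohort_spec(0))


def straight_field(shape=(11, 7, 7), direction=(1.0, 0.0, 0.0), n_samples=2,
                   fraction=0.6, voxel_mm=1.0):
    """Homogeneous single-population field: every voxel points one way."""
    grid = cs.VolumeGrid.isotropic(shape, voxel_mm)
    f = cs.OrientationField.empty(grid, n_samples)
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    f.mean_directions[..., 0, :] = d
    f.fractions[..., 0] = fraction
    f.samples[..., 0, :, :] = d
    return f
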