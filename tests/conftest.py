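import numpy as np
import pytest

import marrowvar as mv


@pytest.fixture(scope="session")
def table1():
    """The bundled per-mouse variance table."""
    return mv.load_table1_fixture()


@pytest.fixture(scope="session")
def small_geom():
    """A compact phantom geometry for fast per-test generation."""
    return mv.PhantomGeometry(
        grid_shape=(12, 12, 20),
        voxel_size=(0.1, 0.1, 0.7),
        bone_axis=2,
        n_slices_proximal=7,
        n_slices_transition=4,
        n_slices_distal=9,
        marrow_radius_voxels=4,
    )


@pytest.fixture()
def healthy_phantom(small_geom):
    vol, mask = mv.generate_volume(small_geom, 50.0, 49.0, seed=1234)
    return vol, mask


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
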