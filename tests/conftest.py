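import numpy as np
import pytest

import bgconn
from bgconn.phantom import MAX_FIBERS


@pytest.fixture(scope="session")
def default_phantom():
    spec = bgconn.default_spec(0)
    labels = bgconn.build_label_volume(spec)
    field = bgconn.build_fiber_field(spec, labels)
    return spec, labels, field


@pytest.fixture(scope="session")
def corridor_phantom():
    spec = bgconn.corridor_spec()
    labels = bgconn.build_label_volume(spec)
    field = bgconn.build_fiber_field(spec, labels)
    return spec, labels, field


def make_field(grid_shape, voxel_size=(1.5, 1.5, 1.5)):
    """Empty FiberField builder for hand-constructed test substrates."""
    return bgconn.FiberField(
        orientations=np.zeros(grid_shape + (MAX_FIBERS, 3)),
        fractions=np.zeros(grid_shape + (MAX_FIBERS,)),
        kappas=np.zeros(grid_shape + (MAX_FIBERS,)),
        nfib=np.zeros(grid_shape, dtype=np.int8),
        voxel_size=voxel_size,
    )


def set_fiber(field, vox, orientation, fraction, kappa=1e18):
    i, j, k = vox
    m = field.nfib[i, j, k]
    v = np.asarray(orientation, dtype=float)
    field.orientations[i, j, k, m] = v / np.linalg.norm(v)
    field.fractions[i, j, k, m] = fraction
    field.kappas[i, j, k, m] = kappa
    field.nfib[i, j, k] = m + 1
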