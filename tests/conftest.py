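import numpy as np
import pytest

from spectac import corrections, phantom, projector
from spectac.pipeline import desk_phantom_spec
from spectac.volume import Volume3D


@pytest.fixture(scope="session")
def desk_spec():
    """Desk-scale phantom spec matching the scaled scanner-A profile."""
    profile = corrections.scanner_a().desk(matrix_size=24, n_views=24, voxel_size_cm=0.90)
    return desk_phantom_spec(profile)


@pytest.fixture(scope="session")
def desk_phantom(desk_spec):
    return phantom.generate_phantom(desk_spec)


@pytest.fixture(scope="session")
def uniform_disc():
    """Noiseless water-equivalent cylinder: emission, mu-map and geometry."""
    n, v = 32, 0.5
    c = (n - 1) / 2
    ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    r = np.sqrt((ii - c) ** 2 + (jj - c) ** 2)
    disc = (r <= 10) & (np.abs(kk - c) <= 10)
    emission = Volume3D(np.where(disc, 1.0, 0.0), v, "counts")
    mumap = Volume3D(np.where(disc, 0.148, 0.0), v, "cm^-1")
    geom = projector.Geometry(32, n, n, v)
    return emission, mumap, geom, disc


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
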