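import numpy as np
import pytest

from earlbench.grids import Grid3D, Image3D
from earlbench.phantoms import make_insert_phantom, make_nema_spheres, rasterize
from earlbench.recon import EARL1, EARL2, emulate_recon


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return Grid3D(dims=(5, 5, 5), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))


@pytest.fixture
def random_image(small_grid, rng):
    return Image3D(small_grid, rng.uniform(0, 10, small_grid.dims))


@pytest.fixture(scope="session")
def insert_truth():
    """Insert phantom rasterized at the default 1 mm truth grid."""
    spec = make_insert_phantom()
    return rasterize(spec, spec.default_grid(spacing_mm=1.0))


@pytest.fixture(scope="session")
def insert_spec():
    return make_insert_phantom()


@pytest.fixture(scope="session")
def nema_truth():
    spec = make_nema_spheres(background_conc=2000.0)
    return rasterize(spec, spec.default_grid(spacing_mm=1.0), supersampling=2)


@pytest.fixture(scope="session")
def nema_recons(nema_truth):
    """Both protocol emulations of the six-sphere phantom."""
    return {
        p.name: emulate_recon(nema_truth.image, p, background_value=2000.0)
        for p in (EARL1, EARL2)
    }
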