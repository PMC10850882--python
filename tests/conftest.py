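import numpy as np
import pytest

from wiseplan import synthetic_heart as sh


@pytest.fixture(scope="session")
def default_patient():
    """One complete synthetic patient at default parameters."""
    return sh.generate_patient(seed=1)


@pytest.fixture(scope="session")
def ischemic_patient():
    """A patient with a non-empty scar set (searched over seeds once)."""
    for seed in range(40):
        pat = sh.generate_patient(seed=seed)
        if pat.gt.scar_segments:
            return pat
    raise RuntimeError("no ischemic patient found in 40 seeds")


def make_slab(nx=31, ny=13, lx=60.0, ly=24.0):
    """Flat rectangular triangle mesh in the z=0 plane."""
    xs = np.linspace(0.0, lx, nx)
    ys = np.linspace(0.0, ly, ny)
    verts = np.array([[x, y, 0.0] for y in ys for x in xs])
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            b = a + 1
            c = a + nx
            d = c + 1
            faces += [(a, b, d), (a, d, c)]
    return verts, np.array(faces, dtype=np.int64)


@pytest.fixture()
def slab():
    return make_slab()
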