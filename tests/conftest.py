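import numpy as np
import pytest

from meshdose.dosimetry import MachineCalibration, PDDModel
from meshdose.phantom import make_ellipsoid_mesh, make_thorax_phantom


@pytest.fixture(scope="session")
def thorax():
    """(PhantomSpec, {name: SurfaceMesh}) — the default nested-quadric thorax."""
    return make_thorax_phantom(seed=1)


@pytest.fixture(scope="session")
def thorax_organs(thorax):
    """trace_beam-style (label, mesh, eta) list."""
    spec, meshes = thorax
    return [(o.label, meshes[o.name], o.eta) for o in spec.organs]


@pytest.fixture(scope="session")
def sphere_mesh():
    """Unit-radius icosphere at subdivision 4 scaled to R = 60 mm."""
    return make_ellipsoid_mesh((0.0, 0.0, 0.0), (60.0, 60.0, 60.0), subdivisions=4)


@pytest.fixture(scope="session")
def pdd_model():
    """6 MV-like demonstration curve (dmax ~ 1.4 cm)."""
    return PDDModel(n=2.25, mu=0.0465)


@pytest.fixture(scope="session")
def calibration():
    return MachineCalibration()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
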