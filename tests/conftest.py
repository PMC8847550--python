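import numpy as np
import pytest
from hypothesis import settings

from callusfe import imaging, meshing, phantom

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def hollow_cylinder_mesh(h_mm, ro=10.0, ri=7.0, length=12.0, density=1000.0):
    """Voxelized hollow cylinder (voxel-centre membership), density-filled."""
    n_xy = int(np.ceil(2 * ro / h_mm)) + 4
    nz = int(round(length / h_mm))
    c = n_xy * h_mm / 2
    x = (np.arange(n_xy) + 0.5) * h_mm - c
    r = np.sqrt(x[:, None] ** 2 + x[None, :] ** 2)
    ann = (r >= ri) & (r <= ro)
    shape = (n_xy, n_xy, nz)
    data = np.where(np.broadcast_to(ann[:, :, None], shape), density, 0.0)
    vol = imaging.DensityVolume(data, h_mm * 1000)
    mask = imaging.BinaryMask(np.broadcast_to(ann[:, :, None], shape).copy(), h_mm * 1000)
    return meshing.voxels_to_hex_mesh(mask, vol)


def analytic_cylinder_vtr(ro_m=0.010, ri_m=0.007, e_pa=1e10, nu=0.3):
    """Closed-form torsional rigidity G*J of a hollow shaft, per degree."""
    g = e_pa / (2 * (1 + nu))
    j = np.pi * (ro_m**4 - ri_m**4) / 2
    return g * j * np.pi / 180.0


@pytest.fixture(scope="session")
def default_spec():
    return phantom.PhantomSpec()


@pytest.fixture(scope="session")
def osteotomy_specimen(default_spec):
    """One meshed osteotomized phantom, shared (read-only) across tests."""
    return phantom.Specimen(
        id="S0",
        dataset_label=1,
        limb_state="operated",
        volume=phantom.generate_osteotomy_phantom(default_spec),
        spec=default_spec,
    )


@pytest.fixture(scope="session")
def small_cylinder_mesh():
    """Coarse hollow cylinder for fast solver-behaviour tests."""
    return hollow_cylinder_mesh(1.0, length=8.0)
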