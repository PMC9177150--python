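import numpy as np
import pytest
import trimesh

from stereomer.models import AnatomyModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ellipsoid_mesh(semi_axes, center, subdivisions=3) -> AnatomyModel:
    """Closed ellipsoid mesh region (vertex depth error ~0.1% of axis)."""
    ico = trimesh.creation.icosphere(subdivisions=subdivisions)
    mesh = trimesh.Trimesh(vertices=ico.vertices * np.asarray(semi_axes, float)
                           + np.asarray(center, float),
                           faces=ico.faces, process=False)
    return AnatomyModel("region", mesh=mesh)


def ellipsoid_volume(semi_axes, center, voxel_mm=0.22, margin_mm=1.5) -> AnatomyModel:
    """Binary label volume of an ellipsoid on an isotropic grid."""
    ax = np.asarray(semi_axes, float)
    c = np.asarray(center, float)
    lo = c - ax - margin_mm
    shape = np.ceil((2 * (ax + margin_mm)) / voxel_mm).astype(int) + 1
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    affine[:3, 3] = lo
    idx = np.indices(shape).reshape(3, -1).T
    centers = idx * voxel_mm + lo
    inside = (((centers - c) / ax) ** 2).sum(axis=1) <= 1.0
    return AnatomyModel("region", volume=inside.reshape(shape), affine=affine)


@pytest.fixture(scope="session")
def rms_cohort():
    """Default-condition cohort in rms mode (fast, shared across tests)."""
    from stereomer import synthetic

    return synthetic.make_cohort(seed=0, signal_mode="rms")
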