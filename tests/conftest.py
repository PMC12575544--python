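import numpy as np
import pytest

from endotwin.materials import ConstitutiveModel


@pytest.fixture(scope="session")
def table_models():
    """The four fitted wall-material models (reference coefficients, MPa)."""
    return {
        "elastic": ConstitutiveModel("elastic", {"e": 0.46}),
        "neo_hookean": ConstitutiveModel("neo_hookean", {"mu": 0.04}),
        "mooney_rivlin": ConstitutiveModel("mooney_rivlin", {"c10": 0.02, "c01": 0.09}),
        "ogden": ConstitutiveModel("ogden", {"mu": [0.20], "alpha": [1.4]}),
    }


@pytest.fixture(scope="session")
def plane_surface():
    """Two-triangle square plane in z=0 with +z inward normals."""
    from endotwin.contact import CollisionSurface
    verts = np.array([[-50.0, -50.0, 0.0], [50.0, -50.0, 0.0],
                      [50.0, 50.0, 0.0], [-50.0, 50.0, 0.0]])
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return CollisionSurface(verts, faces)


@pytest.fixture(scope="session")
def tube_surface():
    """Straight-tube lumen collision surface (inward normals), radius 4.5 mm."""
    from endotwin import phantom
    spec = phantom.VesselSpec(preset="straight_tube", length=100.0,
                              n_rings=20, n_around=16)
    return spec, phantom.make_collision_surface(spec)


@pytest.fixture(scope="session")
def bar_mesh():
    """Structured bar tet mesh with end-vertex index sets."""
    from endotwin import phantom
    verts, tets = phantom.structured_bar(20.0, 4.0, nx=8, ny=2, nz=2)
    left = np.flatnonzero(verts[:, 0] < 1e-9)
    right = np.flatnonzero(verts[:, 0] > 20.0 - 1e-9)
    return verts, tets, left, right


@pytest.fixture(scope="session")
def wobbly_mesh():
    """Small irregular tet mesh (interior vertices perturbed) for FD checks."""
    from endotwin import phantom
    verts, tets = phantom.structured_bar(10.0, 4.0, nx=2, ny=1, nz=2)
    rng = np.random.default_rng(7)
    verts = verts + 0.15 * rng.normal(size=verts.shape)
    return verts, tets


def consistent_end_loads(verts, surface_faces, end_ids, traction):
    """Nodal forces equivalent to a uniform traction on the end face."""
    end_set = set(end_ids.tolist())
    w = np.zeros(len(verts))
    for f in surface_faces:
        if all(v in end_set for v in f):
            area = 0.5 * np.linalg.norm(
                np.cross(verts[f[1]] - verts[f[0]], verts[f[2]] - verts[f[0]]))
            w[f] += area / 3.0
    return np.column_stack([traction * w[end_ids],
                            np.zeros(end_ids.size), np.zeros(end_ids.size)])
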