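import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from endotwin import fem
from endotwin.fem import (ConstantForceField, MeshValidationError, SolveError,
                          build_tet_model, internal_forces, measure_displacement,
                          static_solve, tangent_stiffness)
from endotwin.materials import ConstitutiveModel

from conftest import consistent_end_loads

ELASTIC = ConstitutiveModel("elastic", {"e": 0.46})


def regular_tet_vertices(edge=1.0):
    return edge * np.array([[0.0, 0, 0], [1, 0, 0],
                            [0.5, np.sqrt(3) / 2, 0],
                            [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)]])


class TestBuild:
    def test_unit_regular_tet_volume(self):
        model = build_tet_model(ELASTIC, vertices=regular_tet_vertices(),
                                tets=np.array([[0, 1, 2, 3]]))
        assert model.n_tets == 1
        assert model.volumes[0] == pytest.approx(1.0 / (6.0 * np.sqrt(2)), abs=1e-12)

    def test_negative_orientation_fixed(self):
        model = build_tet_model(ELASTIC, vertices=regular_tet_vertices(),
                                tets=np.array([[0, 2, 1, 3]]))  # inverted ordering
        assert np.all(model.volumes > 0)

    def test_degenerate_tet_rejected(self):
        verts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(MeshValidationError):
            fem.TetModel(vertices=verts, tets=np.array([[0, 1, 2, 3]]),
                         surface_faces=np.zeros((0, 3), dtype=int), material=ELASTIC)

    def test_empty_fixed_set_contract(self, bar_mesh):
        verts, tets, left, right = bar_mesh
        model = build_tet_model(ELASTIC, vertices=verts, tets=tets)
        # dynamics accepted
        a_mat, b_vec = fem.implicit_system(model, np.zeros(model.n_dofs),
                                           np.zeros(model.n_dofs), 1e-3)
        assert a_mat.shape == (model.n_dofs, model.n_dofs)
        # statics rejected
        with pytest.raises(MeshValidationError):
            static_solve(model, ConstantForceField(right, np.array([0, 1e-3, 0])))

    def test_boundary_faces_of_bar(self, bar_mesh):
        verts, tets, *_ = bar_mesh
        faces = fem.boundary_faces(tets)
        # closed box boundary: Euler check V - E + F = 2 on the boundary
        vb = np.unique(faces)
        edges = {tuple(sorted(e)) for f in faces
                 for e in ((f[0], f[1]), (f[1], f[2]), (f[0], f[2]))}
        assert len(vb) - len(edges) + len(faces) == 2

    def test_delaunay_fill_from_watertight_surface(self):
        import trimesh
        box = trimesh.creation.box(extents=(4.0, 4.0, 4.0))
        model = build_tet_model(ELASTIC, surface_mesh=box)
        assert model.n_tets > 0
        assert model.volumes.sum() == pytest.approx(64.0, rel=1e-9)

    def test_open_surface_rejected(self):
        import trimesh
        box = trimesh.creation.box(extents=(4.0, 4.0, 4.0))
        holed = trimesh.Trimesh(vertices=box.vertices, faces=box.faces[:-1],
                                process=False)
        with pytest.raises(MeshValidationError):
            build_tet_model(ELASTIC, surface_mesh=holed)


class TestTangent:
    def test_patch_uniform_strain_exact(self):
        """Single P1 tet under affine displacement carries uniform stress:
        nodal forces equal V * sigma * grad(N_i) exactly."""
        verts = regular_tet_vertices(2.0)
        model = build_tet_model(ELASTIC, vertices=verts,
                                tets=np.array([[0, 1, 2, 3]]),
                                poisson_ratio=0.3, corotational=False)
        eps = np.array([[1e-3, 2e-4, 0.0], [2e-4, -5e-4, 1e-4], [0.0, 1e-4, 3e-4]])
        u = (verts @ eps.T).ravel()
        f, _ = internal_forces(model, u, with_tangent=False)
        e_mod, nu = 0.46, 0.3
        mu, lam = fem._lame(e_mod, nu)
        sigma = lam * np.trace(eps) * np.eye(3) + 2.0 * mu * eps
        grads = np.zeros((4, 3))
        grads[1:] = model.dm_inv[0]
        grads[0] = -grads[1:].sum(axis=0)
        expected = model.volumes[0] * grads @ sigma.T
        np.testing.assert_allclose(f.reshape(4, 3), expected, rtol=1e-10, atol=1e-15)

    def test_elastic_rigid_modes_in_nullspace(self, bar_mesh):
        verts, tets, *_ = bar_mesh
        model = build_tet_model(ELASTIC, vertices=verts, tets=tets)
        k_mat = tangent_stiffness(model, np.zeros(model.n_dofs))
        for vec in np.eye(3):
            rigid = np.tile(vec, model.n_vertices)
            np.testing.assert_allclose(k_mat @ rigid, 0.0, atol=1e-9)

    def test_tangent_symmetry(self, wobbly_mesh, table_models):
        verts, tets = wobbly_mesh
        for kind in ("neo_hookean", "mooney_rivlin", "ogden"):
            model = build_tet_model(table_models[kind], vertices=verts, tets=tets)
            rng = np.random.default_rng(1)
            k_mat = tangent_stiffness(model, 0.05 * rng.normal(size=model.n_dofs))
            asym = abs(k_mat - k_mat.T).max() / abs(k_mat).max()
            assert asym < 1e-8

    def test_neo_hookean_matches_linear_at_rest(self, wobbly_mesh):
        """Small-strain limit: NH tangent at zero displacement equals the
        linear-elastic tangent with matched (mu, lambda)."""
        verts, tets = wobbly_mesh
        nh_mat = ConstitutiveModel("neo_hookean", {"mu": 0.04})
        kappa = fem.default_bulk_penalty(nh_mat)
        e_eq, nu_eq = fem.elastic_moduli_equivalent(nh_mat, kappa)
        m_nh = build_tet_model(nh_mat, vertices=verts, tets=tets, bulk_penalty=kappa)
        m_el = build_tet_model(ConstitutiveModel("elastic", {"e": e_eq}),
                               vertices=verts, tets=tets, poisson_ratio=nu_eq,
                               corotational=False)
        k_nh = tangent_stiffness(m_nh, np.zeros(m_nh.n_dofs)).toarray()
        k_el = tangent_stiffness(m_el, np.zeros(m_el.n_dofs)).toarray()
        scale = np.abs(k_el).max()
        assert np.abs(k_nh - k_el).max() <= 0.05 * scale

    @pytest.mark.parametrize("kind", ["neo_hookean", "mooney_rivlin", "ogden"])
    def test_finite_difference_consistency(self, kind, wobbly_mesh, table_models):
        """Directional derivative of the assembled force matches K @ direction."""
        verts, tets = wobbly_mesh
        model = build_tet_model(table_models[kind], vertices=verts, tets=tets)
        rng = np.random.default_rng(2)
        u0 = 0.03 * rng.normal(size=model.n_dofs)
        f0, k_mat = internal_forces(model, u0)
        d = rng.normal(size=model.n_dofs)
        d /= np.linalg.norm(d)
        h = 1e-6
        fp, _ = internal_forces(model, u0 + h * d, with_tangent=False)
        fm, _ = internal_forces(model, u0 - h * d, with_tangent=False)
        fd = (fp - fm) / (2 * h)
        kd = k_mat @ d
        assert np.linalg.norm(fd - kd) / np.linalg.norm(kd) <= 1e-4

    def test_inverted_element_reported(self, wobbly_mesh):
        verts, tets = wobbly_mesh
        model = build_tet_model(ConstitutiveModel("neo_hookean", {"mu": 0.04}),
                                vertices=verts, tets=tets)
        u = np.zeros((model.n_vertices, 3))
        u[model.tets[0, 0]] = 100.0  # grossly invert local elements
        with pytest.raises(SolveError, match="inverted"):
            internal_forces(model, u.ravel(), with_tangent=False)


class TestStatics:
    def test_zero_force_zero_displacement(self, bar_mesh):
        verts, tets, left, right = bar_mesh
        model = build_tet_model(ELASTIC, vertices=verts, tets=tets,
                                fixed_vertex_ids=left)
        rep = static_solve(model, ConstantForceField(right, np.zeros(3)))
        np.testing.assert_allclose(rep.displacements, 0.0)
        assert np.all(rep.displacements[left] == 0.0)

    def test_pure_linear_superposition(self, bar_mesh):
        verts, tets, left, right = bar_mesh
        model = build_tet_model(ELASTIC, vertices=verts, tets=tets,
                                fixed_vertex_ids=left, corotational=False)
        f1 = ConstantForceField(right, np.array([0.0, 1e-4, 0.0]))
        f2 = ConstantForceField(right, np.array([0.0, 2e-4, 0.0]))
        r1 = static_solve(model, f1)
        r2 = static_solve(model, f2)
        np.testing.assert_allclose(r2.displacements, 2.0 * r1.displacements,
                                   rtol=1e-9, atol=1e-14)

    def test_axial_bar_matches_sigma_l_over_e(self, bar_mesh):
        verts, tets, left, right = bar_mesh
        model = build_tet_model(ELASTIC, vertices=verts, tets=tets,
                                fixed_vertex_ids=left, poisson_ratio=0.0,
                                corotational=False)
        traction = 0.01  # MPa
        forces = consistent_end_loads(verts, model.surface_faces, right, traction)
        rep = static_solve(model, ConstantForceField(right, forces),
                           landmark_ids=right)
        expected = traction * 20.0 / 0.46
        assert rep.displacements[right, 0].mean() == pytest.approx(expected, rel=0.02)

    def test_equilibrium_residual_tolerance(self, bar_mesh):
        verts, tets, left, right = bar_mesh
        model = build_tet_model(ELASTIC, vertices=verts, tets=tets,
                                fixed_vertex_ids=left)
        field_ = ConstantForceField(right, np.array([0.0, 2e-4, 0.0]))
        rep = static_solve(model, field_)
        f_ext = field_.as_vector(model)
        assert rep.residual_norm <= 1e-6 * np.linalg.norm(f_ext)

    def test_force_monotonicity_linear_model(self, bar_mesh):
        """Landmark displacement grows with the applied force magnitude
        (force ratios follow the experiment's low/intermediate/high levels,
        scaled to the small bar fixture)."""
        verts, tets, left, right = bar_mesh
        model = build_tet_model(ELASTIC, vertices=verts, tets=tets,
                                fixed_vertex_ids=left)
        disp = []
        for mag in (0.56e-3, 1.10e-3, 1.63e-3):
            forces = np.tile(mag / right.size * np.array([0.0, 1.0, 0.0]),
                             (right.size, 1))
            rep = static_solve(model, ConstantForceField(right, forces),
                               landmark_ids=right)
            disp.append(rep.landmark_displacements.mean())
        assert disp[0] < disp[1] < disp[2]

    def test_elastic_vs_neo_hookean_small_strain(self, bar_mesh):
        verts, tets, left, right = bar_mesh
        nh_mat = ConstitutiveModel("neo_hookean", {"mu": 0.04})
        kappa = fem.default_bulk_penalty(nh_mat)
        e_eq, nu_eq = fem.elastic_moduli_equivalent(nh_mat, kappa)
        m_el = build_tet_model(ConstitutiveModel("elastic", {"e": e_eq}),
                               vertices=verts, tets=tets, fixed_vertex_ids=left,
                               poisson_ratio=nu_eq)
        m_nh = build_tet_model(nh_mat, vertices=verts, tets=tets,
                               fixed_vertex_ids=left, bulk_penalty=kappa)
        field_ = ConstantForceField(right, np.array([0.0, 5e-5, 0.0]))
        d_el = static_solve(m_el, field_, landmark_ids=right).landmark_displacements
        d_nh = static_solve(m_nh, field_, landmark_ids=right).landmark_displacements
        assert np.abs(d_nh - d_el).max() <= 0.05 * np.abs(d_el).max()


class TestEnergyAndMeasurement:
    def test_hyperelastic_energy_nonnegative(self, wobbly_mesh, table_models):
        verts, tets = wobbly_mesh
        rng = np.random.default_rng(4)
        for kind in ("neo_hookean", "mooney_rivlin", "ogden"):
            model = build_tet_model(table_models[kind], vertices=verts, tets=tets)
            assert fem.total_strain_energy(model, np.zeros(model.n_dofs)) == \
                pytest.approx(0.0, abs=1e-12)
            for _ in range(5):
                u = 0.05 * rng.normal(size=model.n_dofs)
                assert fem.total_strain_energy(model, u) > 0.0

    def test_measure_displacement_oracle(self, bar_mesh):
        verts, tets, left, right = bar_mesh
        model = build_tet_model(ELASTIC, vertices=verts, tets=tets,
                                fixed_vertex_ids=left)
        rng = np.random.default_rng(9)
        disp = 0.01 * rng.normal(size=(model.n_vertices, 3))
        rep = fem.DeformationReport(displacements=disp, applied_force_magnitude=0.0,
                                    landmark_ids=right,
                                    landmark_displacements=np.linalg.norm(
                                        disp[right], axis=1),
                                    residual_norm=0.0, iterations=0)
        per, mx = measure_displacement(model, rep, right)
        np.testing.assert_allclose(per, np.linalg.norm(disp[right], axis=1))
        assert mx == pytest.approx(np.linalg.norm(disp, axis=1).max())

    def test_rigid_translation_measures_its_magnitude(self, bar_mesh):
        verts, tets, left, right = bar_mesh
        model = build_tet_model(ELASTIC, vertices=verts, tets=tets,
                                fixed_vertex_ids=left)
        disp = np.zeros((model.n_vertices, 3))
        disp[right] = [0.0, 5.0, 0.0]
        rep = fem.DeformationReport(displacements=disp, applied_force_magnitude=0.0,
                                    landmark_ids=right,
                                    landmark_displacements=np.linalg.norm(
                                        disp[right], axis=1),
                                    residual_norm=0.0, iterations=0)
        per, _ = measure_displacement(model, rep, right)
        np.testing.assert_allclose(per, 5.0)
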