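import dataclasses

import numpy as np
import pytest

from endotwin import contact as ct
from endotwin.contact import (CollisionSurface, ContactError, ContactParams,
                              closest_points_on_triangles, detect_proximities,
                              resolve_contacts, tangent_basis)

MU = 0.62


def brute_force_detect(points, surface, params):
    """Exhaustive all-pairs point-triangle scan with the local-minimum rule."""
    d, _ = closest_points_on_triangles(points, surface.triangles)
    out = set()
    for pid in range(points.shape[0]):
        for tid in np.flatnonzero(d[pid] < params.alarm_distance):
            dd = d[pid, tid]
            dominated = False
            for other in surface.adjacent_faces(int(tid)):
                if other == tid:
                    continue
                od = d[pid, other]
                if od < dd - 1e-12 or (abs(od - dd) <= 1e-12 and other < tid):
                    dominated = True
                    break
            if not dominated:
                out.add((pid, int(tid)))
    return out


def single_point_solve(pair, params, dt=0.01, mass=1.0, applied=np.zeros(3)):
    """One point mass against a fixed surface: 3-DOF contact solve."""
    basis = tangent_basis(pair.normal)
    jac = np.vstack([pair.normal, basis])
    v_free = dt / mass * np.asarray(applied, dtype=float)
    return resolve_contacts([pair], jac, lambda r: r / mass, v_free, params, dt)


class TestParams:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ContactError):
            ContactParams(alarm_distance=0.5, contact_distance=0.66)
        with pytest.raises(ContactError):
            ContactParams(friction_coefficient=-0.1)


class TestDetection:
    def test_degenerate_triangle_rejected(self):
        verts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ContactError):
            CollisionSurface(verts, np.array([[0, 1, 2]]))

    def test_far_point_detects_nothing(self, plane_surface):
        params = ContactParams(alarm_distance=2.0, contact_distance=0.5)
        pts = np.array([[0.0, 0.0, 4.0]])  # 2x alarm distance away
        assert detect_proximities(pts, plane_surface, params) == []

    def test_two_threshold_activation(self, plane_surface):
        params = ContactParams(alarm_distance=2.0, contact_distance=0.5)
        pairs = detect_proximities(np.array([[3.0, 2.0, 1.2]]), plane_surface, params)
        assert len(pairs) == 1 and pairs[0].status == "candidate"
        pairs = detect_proximities(np.array([[3.0, 2.0, 0.3]]), plane_surface, params)
        assert len(pairs) == 1 and pairs[0].status == "active"
        assert pairs[0].gap == pytest.approx(0.3)

    def test_penetration_gives_negative_gap(self, plane_surface):
        params = ContactParams(alarm_distance=2.0, contact_distance=0.5)
        pairs = detect_proximities(np.array([[3.0, 2.0, -0.2]]), plane_surface, params)
        assert len(pairs) == 1
        assert pairs[0].gap == pytest.approx(-0.2)
        # normal still points into the lumen (+z side)
        assert pairs[0].normal @ np.array([0, 0, 1.0]) > 0

    def test_matches_exhaustive_scan_in_tube(self, tube_surface):
        """Random points inside the tube: implementation equals the oracle."""
        spec, surface = tube_surface
        rng = np.random.default_rng(5)
        n = 500
        pts = np.column_stack([rng.uniform(5, 95, n),
                               rng.uniform(-4.4, 4.4, n),
                               rng.uniform(-4.4, 4.4, n)])
        params = ContactParams(alarm_distance=2.0, contact_distance=0.66)
        impl = {(p.point_id, p.triangle_id)
                for p in detect_proximities(pts, surface, params)}
        assert impl == brute_force_detect(pts, surface, params)

    def test_broad_phase_is_transparent(self, tube_surface):
        spec, surface = tube_surface
        rng = np.random.default_rng(6)
        pts = np.column_stack([rng.uniform(0, 100, 50),
                               rng.uniform(-4, 4, 50), rng.uniform(-4, 4, 50)])
        params = ContactParams(alarm_distance=2.0, contact_distance=0.66)
        with_bp = {(p.point_id, p.triangle_id)
                   for p in detect_proximities(pts, surface, params)}
        without = {(p.point_id, p.triangle_id)
                   for p in detect_proximities(pts, surface, params,
                                               use_broad_phase=False)}
        assert with_bp == without

    def test_closest_point_matches_trimesh(self):
        import trimesh.triangles as tt
        rng = np.random.default_rng(0)
        verts = rng.normal(size=(30, 3))
        faces = rng.integers(0, 30, size=(60, 3))
        ok = ((faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2])
              & (faces[:, 0] != faces[:, 2]))
        tris = verts[faces[ok]]
        pts = rng.normal(size=(40, 3)) * 1.5
        d, _ = closest_points_on_triangles(pts, tris)
        for i, pt in enumerate(pts):
            ref = tt.closest_point(tris, np.repeat(pt[None], len(tris), axis=0))
            d_ref = np.linalg.norm(ref - pt[None], axis=1)
            np.testing.assert_allclose(d[i], d_ref, atol=1e-12)


class TestResolution:
    @pytest.fixture()
    def resting_pair(self, plane_surface):
        params = ContactParams(alarm_distance=2.0, contact_distance=0.5,
                               friction_coefficient=MU)
        pairs = detect_proximities(np.array([[0.0, 0.0, 0.5]]), plane_surface, params)
        return pairs[0], params

    def test_coulomb_stick(self, resting_pair):
        pair, params = resting_pair
        n_push, t_drive = 10.0, 0.5 * MU * 10.0
        basis = tangent_basis(pair.normal)
        res = single_point_solve(pair, params,
                                 applied=-n_push * pair.normal + t_drive * basis[0])
        cf = res.forces[0]
        assert cf.normal_force == pytest.approx(n_push, rel=1e-9)
        assert cf.tangential_force[0] == pytest.approx(-t_drive, rel=1e-9)
        assert abs(res.v_next @ basis[0]) < 1e-12  # no slip

    def test_coulomb_slip(self, resting_pair):
        pair, params = resting_pair
        n_push, t_drive = 10.0, 2.0 * MU * 10.0
        basis = tangent_basis(pair.normal)
        res = single_point_solve(pair, params,
                                 applied=-n_push * pair.normal + t_drive * basis[0])
        cf = res.forces[0]
        assert cf.normal_force == pytest.approx(n_push, rel=1e-9)
        assert np.linalg.norm(cf.tangential_force) == pytest.approx(MU * n_push,
                                                                    rel=1e-9)
        assert cf.tangential_force[0] < 0  # opposes the slip direction
        assert res.v_next @ basis[0] > 0   # sliding persists

    def test_frictionless_limit(self, resting_pair):
        pair, _ = resting_pair
        params0 = ContactParams(alarm_distance=2.0, contact_distance=0.5,
                                friction_coefficient=0.0)
        basis = tangent_basis(pair.normal)
        res = single_point_solve(pair, params0,
                                 applied=-5.0 * pair.normal + 3.0 * basis[0])
        cf = res.forces[0]
        np.testing.assert_allclose(cf.tangential_force, 0.0, atol=1e-12)
        assert cf.normal_force == pytest.approx(5.0, rel=1e-9)

    def test_penetration_removed_within_step(self, plane_surface):
        """A node below the contact surface is pushed back to it in one step."""
        params = ContactParams(alarm_distance=2.0, contact_distance=0.5,
                               friction_coefficient=MU)
        pairs = detect_proximities(np.array([[0.0, 0.0, 0.2]]), plane_surface, params)
        dt = 0.01
        res = single_point_solve(pairs[0], params, dt=dt, applied=[0.0, 0.0, -1.0])
        z_new = 0.2 + dt * float(res.v_next @ np.array([0, 0, 1.0]))
        assert z_new >= params.contact_distance - 1e-3
        assert res.forces[0].normal_force >= 0.0

    def test_residual_history_monotone(self, plane_surface):
        """PGS merit decreases monotonically on the plane fixtures."""
        params = ContactParams(alarm_distance=2.0, contact_distance=0.5,
                               friction_coefficient=MU)
        pts = np.array([[0.0, 0.0, 0.45], [1.5, 0.0, 0.48]])
        pairs = detect_proximities(pts, plane_surface, params)
        assert len(pairs) == 2
        jac = ct.contact_jacobian_points(pairs, 6, dofs_per_node=3)
        mass = 2e-3
        v_free = np.tile([0.1, 0.0, -5.0], 2) * (0.01 / mass)
        res = resolve_contacts(pairs, jac, lambda r: r / mass, v_free, params, 0.01)
        hist = res.residual_history
        assert np.all(np.diff(hist) <= 1e-12)

    def test_empty_pairs_are_identity(self):
        params = ContactParams()
        v = np.arange(6.0)
        res = resolve_contacts([], np.zeros((0, 6)), lambda r: r, v, params, 0.01)
        np.testing.assert_array_equal(res.v_next, v)
        assert res.converged
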