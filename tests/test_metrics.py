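import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from endotwin.metrics import (MetricError, Polyline3D, discrete_frechet,
                              fit_bezier, rigid_register, tip_error)


def naive_frechet(pa, pb):
    """Recursive definition of the discrete Frechet distance, no memoization."""
    def dist(i, j):
        return float(np.linalg.norm(pa[i] - pb[j]))

    def ca(i, j):
        if i == 0 and j == 0:
            return dist(0, 0)
        if i == 0:
            return max(ca(0, j - 1), dist(0, j))
        if j == 0:
            return max(ca(i - 1, 0), dist(i, 0))
        return max(min(ca(i - 1, j), ca(i - 1, j - 1), ca(i, j - 1)), dist(i, j))

    return ca(len(pa) - 1, len(pb) - 1)


class TestRigidRegistration:
    def test_identity(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        xf, rmsd = rigid_register(pts, pts)
        np.testing.assert_allclose(xf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(xf.translation, 0.0, atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(0)
        beads = rng.uniform(-50, 50, size=(6, 3))
        rot = Rotation.from_rotvec([0.3, -0.5, 0.8]).as_matrix()
        trans = np.array([12.0, -7.0, 3.0])
        target = beads @ rot.T + trans
        xf, rmsd = rigid_register(beads, target)
        np.testing.assert_allclose(xf.rotation, rot, atol=1e-10)
        np.testing.assert_allclose(xf.translation, trans, atol=1e-9)
        assert rmsd < 1e-10

    def test_noisy_rmsd_in_expected_band(self):
        """With 0.3 mm isotropic bead noise the post-fit RMSD concentrates
        near the noise scale: mean over 100 seeds inside [0.1, 0.6] mm, single
        seeds never pathologically far outside it."""
        rng = np.random.default_rng(1)
        beads = rng.uniform(-60, 60, size=(6, 3))
        rot = Rotation.from_rotvec([0.1, 0.2, -0.3]).as_matrix()
        rmsds = []
        for seed in range(100):
            noise = np.random.default_rng(seed).normal(0.0, 0.3, size=(6, 3))
            target = beads @ rot.T + np.array([5.0, 1.0, -2.0]) + noise
            _, rmsd = rigid_register(beads, target)
            rmsds.append(rmsd)
        assert 0.1 <= np.mean(rmsds) <= 0.6
        assert min(rmsds) >= 0.05 and max(rmsds) <= 0.9

    def test_collinear_beads_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(MetricError):
            rigid_register(line, line + 1.0)

    def test_count_mismatch_rejected(self):
        with pytest.raises(MetricError):
            rigid_register(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_invariance_to_common_rigid_motion(self):
        """Pre-transforming both bead sets leaves the RMSD unchanged and the
        recovered transform composes with the common motion."""
        rng = np.random.default_rng(3)
        src = rng.uniform(-30, 30, size=(6, 3))
        tgt = src @ Rotation.from_rotvec([0.2, 0.1, 0.4]).as_matrix().T + [1, 2, 3]
        tgt += rng.normal(0, 0.2, size=(6, 3))
        _, rmsd0 = rigid_register(src, tgt)
        common_r = Rotation.from_rotvec([-0.7, 0.5, 0.1]).as_matrix()
        common_t = np.array([40.0, -10.0, 5.0])
        _, rmsd1 = rigid_register(src @ common_r.T + common_t,
                                  tgt @ common_r.T + common_t)
        assert rmsd1 == pytest.approx(rmsd0, rel=1e-9)


class TestTipError:
    def test_identical_paths(self):
        t = np.linspace(0, 1, 20)
        p = Polyline3D(np.column_stack([t * 10, t**2, np.zeros(20)]), timestamps=t)
        mean, series = tip_error(p, p)
        assert mean == pytest.approx(0.0, abs=1e-14)
        assert series.shape == (20,)

    def test_constant_offset(self):
        t = np.linspace(0, 1, 15)
        pts = np.column_stack([t * 10, np.sin(t), np.zeros(15)])
        a = Polyline3D(pts, timestamps=t)
        b = Polyline3D(pts + [3.0, 0.0, 0.0], timestamps=t)
        mean, _ = tip_error(a, b)
        assert mean == pytest.approx(3.0)

    def test_matches_direct_norm_average(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 2, 25))
        pa = rng.normal(size=(25, 3))
        pb = rng.normal(size=(25, 3))
        mean, series = tip_error(Polyline3D(pa, timestamps=t),
                                 Polyline3D(pb, timestamps=t), pairing="by_time")
        direct = np.linalg.norm(pa - pb, axis=1)
        np.testing.assert_allclose(series, direct, atol=1e-12)
        assert mean == pytest.approx(direct.mean())

    def test_disjoint_time_ranges_rejected(self):
        a = Polyline3D(np.zeros((3, 3)), timestamps=np.array([0.0, 1, 2]))
        b = Polyline3D(np.zeros((3, 3)), timestamps=np.array([5.0, 6, 7]))
        with pytest.raises(MetricError):
            tip_error(a, b, pairing="by_time")

    def test_arclength_pairing_without_timestamps(self):
        a = Polyline3D(np.column_stack([np.linspace(0, 10, 11),
                                        np.zeros(11), np.zeros(11)]))
        b = Polyline3D(np.column_stack([np.linspace(0, 10, 23),
                                        np.ones(23), np.zeros(23)]))
        mean, _ = tip_error(a, b)
        assert mean == pytest.approx(1.0)


class TestFrechet:
    def test_identical_zero(self):
        p = np.random.default_rng(0).normal(size=(12, 3))
        assert discrete_frechet(p, p) == 0.0

    def test_parallel_offset(self):
        x = np.linspace(0, 10, 9)
        a = np.column_stack([x, np.zeros(9), np.zeros(9)])
        b = a + [0.0, 2.5, 0.0]
        assert discrete_frechet(a, b) == pytest.approx(2.5)

    def test_matches_naive_recursion(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            na, nb = rng.integers(2, 9, size=2)
            pa = rng.normal(size=(na, 3))
            pb = rng.normal(size=(nb, 3))
            assert discrete_frechet(pa, pb) == pytest.approx(
                naive_frechet(pa, pb), abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_symmetry_and_lower_bounds(self, seed):
        rng = np.random.default_rng(seed)
        pa = rng.normal(size=(rng.integers(2, 10), 3))
        pb = rng.normal(size=(rng.integers(2, 10), 3))
        d = discrete_frechet(pa, pb)
        assert d == pytest.approx(discrete_frechet(pb, pa), abs=1e-12)
        endpoints = max(np.linalg.norm(pa[0] - pb[0]),
                        np.linalg.norm(pa[-1] - pb[-1]))
        assert d >= endpoints - 1e-12
        # directed-Hausdorff lower bound
        cross = np.linalg.norm(pa[:, None] - pb[None], axis=2)
        hausdorff = max(cross.min(axis=1).max(), cross.min(axis=0).max())
        assert d >= hausdorff - 1e-12

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25)
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        pa, pb, pc = (rng.normal(size=(rng.integers(2, 8), 3)) for _ in range(3))
        dab = discrete_frechet(pa, pb)
        dbc = discrete_frechet(pb, pc)
        dac = discrete_frechet(pa, pc)
        assert dac <= dab + dbc + 1e-12


class TestBezier:
    def test_collinear_stays_collinear(self):
        pts = np.column_stack([np.linspace(0, 10, 12), np.zeros(12), np.zeros(12)])
        control, curve = fit_bezier(pts, degree=3)
        assert np.abs(curve[:, 1:]).max() < 1e-9
        assert np.abs(control[:, 1:]).max() < 1e-9

    def test_round_trip_degree_three(self):
        control_true = np.array([[0.0, 0, 0], [3, 5, 1], [7, -2, 2], [10, 1, 0]])
        t = np.linspace(0, 1, 40)
        basis = np.stack([(1 - t)**3, 3 * t * (1 - t)**2,
                          3 * t**2 * (1 - t), t**3], axis=1)
        pts = basis @ control_true
        control, _ = fit_bezier(pts, degree=3)
        np.testing.assert_allclose(control, control_true, atol=1e-7)
        # residual of the fitted curve against the samples
        _, curve = fit_bezier(pts, degree=3, n_samples=40)
        # endpoints interpolated exactly
        np.testing.assert_allclose(curve[0], pts[0], atol=1e-12)
        np.testing.assert_allclose(curve[-1], pts[-1], atol=1e-12)

    def test_residual_nonincreasing_in_degree(self):
        """Nested least squares: richer Bezier families fit no worse."""
        rng = np.random.default_rng(11)
        t = np.linspace(0, 1, 30)
        pts = np.column_stack([10 * t, np.sin(3 * t), np.cos(2 * t)])
        pts += 0.05 * rng.normal(size=pts.shape)

        def residual(degree):
            _, curve = fit_bezier(pts, degree=degree, n_samples=800)
            dists = np.linalg.norm(pts[:, None] - curve[None], axis=2).min(axis=1)
            return float(np.linalg.norm(dists))

        r2, r3, r4 = residual(2), residual(3), residual(4)
        assert r2 >= r3 - 1e-6 >= r4 - 2e-6

    def test_degree_bounds(self):
        pts = np.zeros((3, 3))
        with pytest.raises(MetricError):
            fit_bezier(pts, degree=3)
        with pytest.raises(MetricError):
            fit_bezier(np.zeros((10, 3)), degree=1)


class TestPolyline:
    def test_validation(self):
        with pytest.raises(MetricError):
            Polyline3D(np.zeros((1, 3)))
        with pytest.raises(MetricError):
            Polyline3D(np.array([[0.0, 0, 0], [np.nan, 0, 0]]))
        with pytest.raises(MetricError):
            Polyline3D(np.zeros((3, 3)), timestamps=np.array([0.0, 2.0, 1.0]))

    def test_ap_projection_drops_one_axis(self):
        p = Polyline3D(np.array([[1.0, 2, 3], [4, 5, 6]]))
        flat = p.project_2d(drop_axis=2)
        np.testing.assert_array_equal(flat.points[:, 2], 0.0)
        np.testing.assert_array_equal(flat.points[:, :2], p.points[:, :2])

    def test_csv_round_trip(self, tmp_path):
        t = np.linspace(0, 1, 8)
        pts = np.column_stack([t * 13, np.sin(t), np.zeros(8)])
        path = tmp_path / "tip.csv"
        with open(path, "w") as fh:
            fh.write("t,x,y,z\n")
            for ti, (x, y, z) in zip(t, pts):
                fh.write(f"{ti},{x},{y},{z}\n")
        back = Polyline3D.from_csv(path)
        np.testing.assert_allclose(back.points, pts)
        np.testing.assert_allclose(back.timestamps, t)
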