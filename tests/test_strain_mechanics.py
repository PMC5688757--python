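"""Affine fitting, polar decomposition, strain axes and group statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from retinamech import strain_mechanics as sm
from retinamech.ridge_analysis import ColumnDirection
from retinamech.surface_projection import TiltPlane
from retinamech.strain_mechanics import PointCorrespondence


def rot(deg):
    r = math.radians(deg)
    return np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])


@pytest.fixture
def cloud():
    rng = np.random.default_rng(1)
    return rng.uniform(-10, 10, (25, 2))


class TestCorrectTilt:
    def test_zero_tilt_is_identity(self, cloud):
        plane = TiltPlane(np.array([0.0, 0.0, 1.0]), 5.0)
        np.testing.assert_allclose(sm.correct_tilt(cloud, plane), cloud)

    def test_tilted_plane_distances_restored(self, cloud):
        # place the cloud on a plane tilted 10 degrees about y
        th = math.radians(10.0)
        n = np.array([math.sin(th), 0.0, math.cos(th)])
        pts3 = np.column_stack([cloud, (20.0 - cloud @ n[:2]) / n[2]])
        corrected = sm.correct_tilt(pts3, TiltPlane(n, 20.0))
        # true in-plane distances from the 3D embedding
        d3 = np.linalg.norm(pts3[:, None] - pts3[None, :], axis=-1)
        d2 = np.linalg.norm(corrected[:, None] - corrected[None, :], axis=-1)
        np.testing.assert_allclose(d2, d3, atol=1e-9)

    def test_2d_points_lifted_onto_plane(self, cloud):
        th = math.radians(8.0)
        n = np.array([0.0, math.sin(th), math.cos(th)])
        plane = TiltPlane(n, 12.0)
        corrected = sm.correct_tilt(cloud, plane)
        pts3 = np.column_stack([cloud, plane.z_at(cloud[:, 0], cloud[:, 1])])
        d3 = np.linalg.norm(pts3[:, None] - pts3[None, :], axis=-1)
        d2 = np.linalg.norm(corrected[:, None] - corrected[None, :], axis=-1)
        np.testing.assert_allclose(d2, d3, atol=1e-9)


class TestFitAffine:
    def test_identity_on_unmoved_points(self, cloud):
        fit = sm.fit_affine(PointCorrespondence(cloud, cloud))
        np.testing.assert_allclose(fit.M, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(fit.b, 0.0, atol=1e-12)

    def test_exact_recovery_of_known_transform(self, cloud):
        M0 = np.array([[1.2, 0.0], [0.0, 0.9]])
        b0 = np.array([0.5, -0.3])
        fit = sm.fit_affine(PointCorrespondence(cloud, cloud @ M0.T + b0))
        np.testing.assert_allclose(fit.M, M0, atol=1e-12)
        np.testing.assert_allclose(fit.b, b0, atol=1e-12)

    def test_least_squares_beats_random_perturbations(self, cloud):
        rng = np.random.default_rng(2)
        rf = cloud @ rot(5.0).T * 1.1 + rng.normal(0, 0.3, cloud.shape)
        pc = PointCorrespondence(cloud, rf)
        fit = sm.fit_affine(pc)

        def objective(M, b):
            return ((rf - cloud @ M.T - b) ** 2).sum()

        best = objective(fit.M, fit.b)
        for scale in (1e-4, 1e-3, 1e-2, 1e-1):
            dM = rng.normal(0, scale, (2500, 2, 2))
            db = rng.normal(0, scale, (2500, 2))
            for k in range(2500):
                assert best <= objective(fit.M + dM[k], fit.b + db[k]) + 1e-12

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError):
            sm.fit_affine(PointCorrespondence(line, line))


class TestResidualFraction:
    def test_exact_affine_gives_zero(self, cloud):
        pc = PointCorrespondence(cloud, cloud * 1.1)
        assert sm.residual_fraction(pc, sm.fit_affine(pc), 5.0) == pytest.approx(0.0)

    def test_fixed_displacement_gives_eps_over_distance(self, cloud):
        eps = 0.7
        fit = sm.fit_affine(PointCorrespondence(cloud, cloud))
        shifted = cloud + eps * np.array([1.0, 0.0])
        # residual against the identity fit: every point off by eps
        pc = PointCorrespondence(cloud, shifted)
        ident = sm.AffineTransform(np.eye(2), np.zeros(2))
        assert sm.residual_fraction(pc, ident, 5.0) == pytest.approx(eps / 5.0)
        del fit

    def test_monotone_in_noise(self, cloud):
        rng = np.random.default_rng(3)
        fracs = []
        for sd in (0.05, 0.2, 0.8):
            rf = cloud + rng.normal(0, sd, cloud.shape)
            pc = PointCorrespondence(cloud, rf)
            fracs.append(sm.residual_fraction(pc, sm.fit_affine(pc), 5.0))
        assert fracs[0] < fracs[1] < fracs[2]


class TestNeighborDistance:
    def test_unit_grid(self):
        gx, gy = np.meshgrid(np.arange(5.0), np.arange(4.0))
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        assert sm.typical_neighbor_distance(pts) == pytest.approx(1.0)

    def test_lattice_spacing_recovered(self, lattice):
        d = sm.typical_neighbor_distance(lattice.positions)
        assert d == pytest.approx(lattice.spacing)

    def test_scale_equivariance(self, cloud):
        a = sm.typical_neighbor_distance(cloud)
        b = sm.typical_neighbor_distance(cloud * 3.0)
        assert b == pytest.approx(3.0 * a)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            sm.typical_neighbor_distance(np.zeros((1, 2)))


class TestPolarDecompose:
    def test_identity(self):
        U, P = sm.polar_decompose(np.eye(2))
        np.testing.assert_allclose(U, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(P, np.eye(2), atol=1e-12)

    def test_rotation_times_stretch_by_construction(self):
        M = rot(30.0) @ np.diag([1.3, 0.8])
        U, P = sm.polar_decompose(M)
        np.testing.assert_allclose(U, rot(30.0), atol=1e-10)
        np.testing.assert_allclose(sorted(np.linalg.eigvalsh(P)), [0.8, 1.3],
                                   atol=1e-10)

    def test_thousand_random_matrices_against_svd_oracle(self):
        """U P = M, U orthogonal, P symmetric PSD, and P equal to the
        SVD-based construction V diag(s) V', all within 1e-10."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            M = rng.normal(0, 1, (2, 2))
            U, P = sm.polar_decompose(M)
            np.testing.assert_allclose(U @ P, M, atol=1e-10)
            np.testing.assert_allclose(U.T @ U, np.eye(2), atol=1e-10)
            np.testing.assert_allclose(P, P.T, atol=1e-10)
            assert np.linalg.eigvalsh(P).min() >= -1e-10
            W, s, Vt = np.linalg.svd(M)
            np.testing.assert_allclose(P, Vt.T @ np.diag(s) @ Vt, atol=1e-10)
            np.testing.assert_allclose(U, W @ Vt, atol=1e-8)

    @given(st.integers(0, 10_000))
    def test_det_p_equals_abs_det_m(self, seed):
        M = np.random.default_rng(seed).normal(0, 2, (2, 2))
        _, P = sm.polar_decompose(M)
        assert np.linalg.det(P) == pytest.approx(abs(np.linalg.det(M)), abs=1e-10)

    def test_singular_matrix_handled(self):
        M = np.array([[1.0, 0.0], [0.0, 0.0]])
        U, P = sm.polar_decompose(M)
        np.testing.assert_allclose(U @ P, M, atol=1e-10)


class TestStrainAxes:
    def test_columns_along_y_assigns_y_strain(self):
        sx, sy, dev, indet = sm.strain_axes(np.diag([1.0, 1.2]),
                                            ColumnDirection(90.0, 1.0))
        assert (sx, sy) == (1.0, 1.2)
        assert dev == pytest.approx(0.0)
        assert not indet

    @pytest.mark.parametrize("delta", [15.0, 40.0, 90.0])
    def test_equivariance_under_common_rotation(self, delta):
        P0 = np.diag([0.9, 1.25])
        R = rot(delta)
        sx, sy, dev, _ = sm.strain_axes(R @ P0 @ R.T,
                                        ColumnDirection(90.0 + delta, 1.0))
        assert sx == pytest.approx(0.9, abs=1e-10)
        assert sy == pytest.approx(1.25, abs=1e-10)
        assert dev == pytest.approx(0.0, abs=1e-6)

    def test_isotropic_axes_indeterminate(self):
        sx, sy, dev, indet = sm.strain_axes(1.1 * np.eye(2),
                                            ColumnDirection(90.0, 1.0))
        assert indet and sx == sy == pytest.approx(1.1)
        assert math.isnan(dev)


class TestStats:
    def test_identical_groups_boundary(self):
        a = np.array([1.0, 1.1, 1.2, 0.9])
        t, p, df = sm.welch_t_test(a, a)
        assert t == 0.0 and p == pytest.approx(1.0)
        A = np.column_stack([a, [0.3, 0.8, 0.1, 0.6]])
        t2, ph = sm.hotelling_unequal(A, A.copy())
        assert t2 == 0.0 and ph == 1.0

    def test_swapping_groups_negates_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(1.2, 0.1, 10), rng.normal(1.0, 0.2, 12)
        t1, p1, _ = sm.welch_t_test(a, b)
        t2, p2, _ = sm.welch_t_test(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_hotelling_affine_invariance(self):
        rng = np.random.default_rng(6)
        A = rng.normal(0, 1, (15, 2)) + [0.5, 0.2]
        B = rng.normal(0, 1, (12, 2))
        L = np.array([[2.0, 0.3], [-0.5, 1.0]])
        t2a, pa = sm.hotelling_unequal(A, B)
        t2b, pb = sm.hotelling_unequal(A @ L.T + 3.0, B @ L.T + 3.0)
        assert t2a == pytest.approx(t2b) and pa == pytest.approx(pb)

    def test_undersized_groups_rejected(self):
        with pytest.raises(ValueError):
            sm.welch_t_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            sm.hotelling_unequal(np.zeros((3, 2)), np.ones((8, 2)))


class TestRunExperiment:
    def test_control_noise_free_strains_exactly_one(self, lattice):
        from retinamech import synthetic_data as sd
        exp = sd.simulate_ablation_recoil(
            lattice, tuple(lattice.positions.mean(0)), 7.0,
            strain_true=(1.0, 1.3), group="CONTROL", noise_sd=0.0,
        )
        _, table = sm.run_strain_experiment(exp, ColumnDirection(90.0, 1.0))
        np.testing.assert_allclose(table["x_strain"], 1.0, atol=1e-12)
        np.testing.assert_allclose(table["y_strain"], 1.0, atol=1e-12)

    def test_ablation_noise_free_recovers_truth_at_each_time(self, lattice):
        from retinamech import synthetic_data as sd
        exp = sd.simulate_ablation_recoil(
            lattice, tuple(lattice.positions.mean(0)), 7.0,
            strain_true=(1.0, 1.2), noise_sd=0.0, n_tracked=24,
        )
        results, table = sm.run_strain_experiment(exp, ColumnDirection(90.0, 1.0))
        for r, t in zip(results, exp.times_min):
            f = exp.saturation(t)
            assert r.x_strain == pytest.approx(1.0, abs=1e-10)
            assert r.y_strain == pytest.approx(1.0 + 0.2 * f, abs=1e-10)
            assert r.residual_fraction == pytest.approx(0.0, abs=1e-10)

    def test_strain_invariant_under_rigid_rotation_of_both_sets(self, lattice):
        from retinamech import synthetic_data as sd
        exp = sd.simulate_ablation_recoil(
            lattice, tuple(lattice.positions.mean(0)), 7.0,
            strain_true=(0.95, 1.25), noise_sd=0.0, n_tracked=20,
        )
        pc = PointCorrespondence(exp.points_pre, exp.points_post[-1])
        R = rot(25.0)
        pc_rot = PointCorrespondence(exp.points_pre @ R.T, exp.points_post[-1] @ R.T)
        e1 = np.sort(np.linalg.eigvalsh(sm.polar_decompose(sm.fit_affine(pc).M)[1]))
        e2 = np.sort(np.linalg.eigvalsh(sm.polar_decompose(sm.fit_affine(pc_rot).M)[1]))
        np.testing.assert_allclose(e1, e2, atol=1e-10)

    def test_axis_assignment_robust_to_theta_jitter(self, lattice):
        """With the column direction known only to +-10 deg, the y-assigned
        axis still deviates by at most 20 deg in at least 90% of runs."""
        from retinamech import synthetic_data as sd
        center = tuple(lattice.positions.mean(0))
        rng = np.random.default_rng(7)
        ok = 0
        n = 50
        for seed in range(n):
            exp = sd.simulate_ablation_recoil(
                lattice, center, 7.0, strain_true=(1.0, 1.2),
                noise_sd=0.02 * lattice.spacing, seed=seed, n_tracked=20,
            )
            theta = ColumnDirection(90.0 + rng.uniform(-10, 10), 1.0)
            results, _ = sm.run_strain_experiment(exp, theta)
            if abs(results[-1].axis_deviation_deg) <= 20.0:
                ok += 1
        assert ok >= 0.9 * n
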