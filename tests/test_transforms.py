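import json

import numpy as np
import pytest

from siftreg.transforms import (
    AffineTransform3D,
    DegenerateGeometryError,
    SingularTransformError,
    TPSTransform3D,
    apply_transform,
    fit_affine_lsq,
    fit_tps,
    invert_affine,
    invert_map_points,
    ransac_affine,
    tps_parameter_count,
    transform_from_dict,
    transform_to_dict,
)


def random_rigid(rng, max_angle=0.5):
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    a = rng.uniform(-max_angle, max_angle)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
    return AffineTransform3D(R, rng.uniform(-30, 30, 3))


class TestFitAffine:
    def test_identity(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(-50, 50, (10, 3))
        t = fit_affine_lsq(p, p)
        assert np.allclose(t.linear, np.eye(3), atol=1e-9)
        assert np.allclose(t.translation, 0, atol=1e-9)

    def test_recovers_rigid_motion(self):
        rng = np.random.default_rng(1)
        truth = random_rigid(rng)
        p = rng.uniform(-50, 50, (10, 3))
        fit = fit_affine_lsq(p, truth(p))
        assert np.allclose(fit.linear, truth.linear, atol=1e-8)
        assert np.allclose(fit.translation, truth.translation, atol=1e-8)

    def test_coplanar_points_raise(self):
        p = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        with pytest.raises(DegenerateGeometryError):
            fit_affine_lsq(p, p)

    def test_too_few_points(self):
        p = np.zeros((3, 3))
        with pytest.raises(ValueError):
            fit_affine_lsq(p, p)

    def test_matches_normal_equations_oracle(self):
        # closed form: [A | t] = (X^T X)^{-1} X^T Q with X = [P 1]
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(-80, 80, (rng.integers(4, 40), 3))
            if np.linalg.matrix_rank(p - p.mean(0)) < 3:
                continue
            q = p @ rng.uniform(-2, 2, (3, 3)) + rng.uniform(-10, 10, 3)
            q += 0.5 * rng.standard_normal(q.shape)
            X = np.hstack([p, np.ones((len(p), 1))])
            sol = np.linalg.inv(X.T @ X) @ X.T @ q
            fit = fit_affine_lsq(p, q)
            assert np.allclose(fit.linear, sol[:3].T, atol=1e-8)
            assert np.allclose(fit.translation, sol[3], atol=1e-8)


class TestRansac:
    def simulate(self, rng, n_in=60, n_out=40, noise=1.0):
        truth = random_rigid(rng, max_angle=0.3)
        src_in = rng.uniform(-100, 100, (n_in, 3))
        dst_in = truth(src_in) + noise * rng.standard_normal((n_in, 3))
        src_out = rng.uniform(-100, 100, (n_out, 3))
        dst_out = rng.uniform(-100, 100, (n_out, 3))
        src = np.vstack([src_in, src_out])
        dst = np.vstack([dst_in, dst_out])
        return truth, src, dst, np.arange(len(src)) < n_in

    def test_outlier_free_case_uses_all(self):
        rng = np.random.default_rng(3)
        truth = random_rigid(rng)
        src = rng.uniform(-100, 100, (40, 3))
        res = ransac_affine(src, truth(src), threshold=10.0, seed=0)
        assert res.success
        assert res.inlier_mask.all()
        direct = fit_affine_lsq(src, truth(src))
        assert np.allclose(res.transform.linear, direct.linear, atol=1e-6)
        assert np.allclose(res.transform.translation, direct.translation, atol=1e-6)

    def test_recovery_with_outliers(self):
        rng = np.random.default_rng(4)
        truth, src, dst, is_inlier = self.simulate(rng)
        res = ransac_affine(src, dst, threshold=10.0, seed=1)
        assert res.success
        assert np.linalg.norm(res.transform.translation - truth.translation) <= 2.0
        assert (res.inlier_mask & is_inlier).sum() >= 55
        assert (res.inlier_mask & ~is_inlier).sum() <= 2

    def test_determinism(self):
        rng = np.random.default_rng(5)
        _, src, dst, _ = self.simulate(rng)
        a = ransac_affine(src, dst, threshold=10.0, seed=42)
        b = ransac_affine(src, dst, threshold=10.0, seed=42)
        assert np.array_equal(a.inlier_mask, b.inlier_mask)
        assert np.array_equal(a.transform.linear, b.transform.linear)
        assert a.n_iterations == b.n_iterations

    def test_too_few_matches_raise(self):
        with pytest.raises(ValueError):
            ransac_affine(np.zeros((3, 3)), np.zeros((3, 3)), threshold=10.0)

    def test_failure_is_distinguishable(self):
        # pure noise with a tiny threshold: no 4-inlier consensus model
        rng = np.random.default_rng(6)
        src = rng.uniform(-100, 100, (12, 3))
        dst = rng.uniform(-100, 100, (12, 3))
        res = ransac_affine(src, dst, threshold=1e-9, seed=0, max_iterations=200)
        assert not res.success
        assert res.transform is None
        assert res.n_inliers == 0

    def test_inlier_residuals_bounded_by_threshold(self):
        rng = np.random.default_rng(7)
        _, src, dst, _ = self.simulate(rng)
        res = ransac_affine(src, dst, threshold=10.0, seed=2)
        resid = np.linalg.norm(res.transform(src) - dst, axis=1)
        assert np.all(resid[res.inlier_mask] <= 10.0)
        assert res.n_inliers >= 4


class TestTPS:
    def test_affine_reproduction(self):
        rng = np.random.default_rng(8)
        truth = random_rigid(rng)
        src = rng.uniform(-60, 60, (12, 3))
        tps = fit_tps(src, truth(src), regularization=0.0)
        assert np.max(np.abs(tps.weights)) <= 1e-8
        grid = rng.uniform(-80, 80, (50, 3))
        assert np.allclose(tps(grid), truth(grid), atol=1e-6)

    def test_exact_interpolation(self):
        rng = np.random.default_rng(9)
        src = rng.uniform(-50, 50, (10, 3))
        tgt = src + rng.uniform(-5, 5, (10, 3))
        tps = fit_tps(src, tgt, regularization=0.0)
        assert np.max(np.linalg.norm(tps(src) - tgt, axis=1)) <= 1e-6

    def test_side_conditions(self):
        rng = np.random.default_rng(10)
        src = rng.uniform(-50, 50, (15, 3))
        tgt = src + rng.uniform(-8, 8, (15, 3))
        tps = fit_tps(src, tgt)
        assert np.all(np.abs(tps.weights.sum(axis=0)) <= 1e-8)
        moments = tps.control_points.T @ tps.weights
        assert np.all(np.abs(moments) <= 1e-6)

    def test_regularization_monotone_residual(self):
        rng = np.random.default_rng(11)
        src = rng.uniform(-50, 50, (20, 3))
        tgt = src + rng.uniform(-6, 6, (20, 3))
        resid = []
        for lam in (0.0, 0.1, 1.0, 10.0, 100.0):
            tps = fit_tps(src, tgt, regularization=lam)
            resid.append(np.linalg.norm(tps(src) - tgt, axis=1).mean())
        assert np.all(np.diff(resid) >= -1e-9)

    def test_parameter_count(self):
        assert tps_parameter_count(0) == 12
        assert tps_parameter_count(1) == 15
        assert tps_parameter_count(6) == 30
        assert tps_parameter_count(100) == 312
        with pytest.raises(ValueError):
            tps_parameter_count(-1)
        rng = np.random.default_rng(12)
        src = rng.uniform(-50, 50, (6, 3))
        tps = fit_tps(src, src + 1.0)
        assert tps.n_parameters == 30

    def test_duplicate_sources_raise(self):
        src = np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1], [2, 0, 1], [0, 3, 2]], dtype=float)
        with pytest.raises(DegenerateGeometryError):
            fit_tps(src, src)

    def test_coplanar_sources_raise(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 3, 0]], dtype=float)
        with pytest.raises(DegenerateGeometryError):
            fit_tps(src, src)


class TestApplyInvert:
    def test_identity_affine(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(-10, 10, (5, 3))
        assert np.allclose(apply_transform(AffineTransform3D.identity(), p), p)

    def test_tps_identity_and_control_points(self):
        rng = np.random.default_rng(14)
        src = rng.uniform(-50, 50, (8, 3))
        tps_id = fit_tps(src, src)
        p = rng.uniform(-60, 60, (20, 3))
        assert np.allclose(tps_id(p), p, atol=1e-6)
        tgt = src + rng.uniform(-5, 5, (8, 3))
        tps = fit_tps(src, tgt)
        assert np.allclose(tps(src), tgt, atol=1e-6)

    def test_affine_inverse_round_trip(self):
        rng = np.random.default_rng(15)
        t = AffineTransform3D(rng.uniform(-1, 1, (3, 3)) + 2 * np.eye(3), rng.uniform(-20, 20, 3))
        inv = invert_affine(t)
        p = rng.uniform(-100, 100, (100, 3))
        assert np.allclose(inv(t(p)), p, atol=1e-9)
        assert np.allclose(t(inv(p)), p, atol=1e-9)

    def test_singular_affine_rejected(self):
        m = np.eye(3)
        m[1] = 0.0
        with pytest.raises(SingularTransformError):
            AffineTransform3D(m, np.zeros(3))

    def test_numeric_tps_inversion(self):
        rng = np.random.default_rng(16)
        src = rng.uniform(-50, 50, (10, 3))
        tgt = src + rng.uniform(-4, 4, (10, 3))
        tps = fit_tps(src, tgt)
        p = rng.uniform(-40, 40, (30, 3))
        q = tps(p)
        affine0 = AffineTransform3D(tps.linear, tps.translation)
        back, conv = invert_map_points(tps, q, initializer=affine0, tol=1e-8)
        assert conv.all()
        assert np.allclose(back, p, atol=1e-6)


class TestSerialization:
    def test_affine_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(17)
        t = AffineTransform3D(rng.standard_normal((3, 3)) + 3 * np.eye(3), rng.standard_normal(3))
        d = json.loads(json.dumps(transform_to_dict(t)))
        back = transform_from_dict(d)
        assert np.array_equal(back.linear, t.linear)
        assert np.array_equal(back.translation, t.translation)
        assert d["convention"] == "cbct_to_ct"

    def test_tps_round_trip_bit_exact(self):
        rng = np.random.default_rng(18)
        src = rng.uniform(-50, 50, (7, 3))
        tps = fit_tps(src, src + rng.uniform(-3, 3, (7, 3)))
        back = transform_from_dict(json.loads(json.dumps(transform_to_dict(tps))))
        assert np.array_equal(back.control_points, tps.control_points)
        assert np.array_equal(back.weights, tps.weights)
        assert np.array_equal(back.linear, tps.linear)
        p = rng.uniform(-60, 60, (5, 3))
        assert np.array_equal(back(p), tps(p))
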