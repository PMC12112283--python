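import math

import numpy as np
import pytest

from geofilter import (
    BilateralParams,
    DiffusionParams,
    ImageGrid,
    LmsParams,
    bilateral_filter,
    classify_inliers,
    conductance,
    curvature_anisotropic_diffusion,
    fit_polynomial_window,
    gradient_anisotropic_diffusion,
    lms_filter,
    lms_ransac,
    min_sample_size,
    ransac_iterations,
    robust_threshold,
)
from geofilter.baselines import SingularFitError
from conftest import random_image


# --------------------------------------------------------------------------
# independent straight-line re-evaluations (no shared code with the package)

def naive_gad_step(plane, C, tau, form):
    H, W = plane.shape
    out = plane.copy()
    for y in range(H):
        for x in range(W):
            flux = 0.0
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                yy = min(max(y + dy, 0), H - 1)
                xx = min(max(x + dx, 0), W - 1)
                d = plane[yy, xx] - plane[y, x]
                if form == "exponential":
                    g = math.exp(-(d * d) / (C * C))
                else:
                    g = 1.0 / (1.0 + (d * d) / (C * C))
                flux += g * d
            out[y, x] = plane[y, x] + tau * flux
    return out


def naive_cad_step(plane, C, tau, form, eps=1e-8):
    H, W = plane.shape

    def at(a, y, x):
        return a[min(max(y, 0), H - 1), min(max(x, 0), W - 1)]

    gx = np.array([[(at(plane, y, x + 1) - at(plane, y, x - 1)) / 2 for x in range(W)] for y in range(H)])
    gy = np.array([[(at(plane, y + 1, x) - at(plane, y - 1, x)) / 2 for x in range(W)] for y in range(H)])
    mag = np.sqrt(gx**2 + gy**2)
    nx, ny = gx / (mag + eps), gy / (mag + eps)
    kap = np.array(
        [
            [
                (at(nx, y, x + 1) - at(nx, y, x - 1)) / 2 + (at(ny, y + 1, x) - at(ny, y - 1, x)) / 2
                for x in range(W)
            ]
            for y in range(H)
        ]
    )
    if form == "exponential":
        g = np.exp(-(kap**2) / (C * C))
    else:
        g = 1.0 / (1.0 + kap**2 / (C * C))
    return plane + tau * g * mag * kap


class TestConductance:
    def test_zero_gradient(self):
        assert conductance(0.0, 3.0, "exponential") == 1.0
        assert conductance(0.0, 3.0, "rational") == 1.0

    def test_at_scale(self):
        assert conductance(5.0, 5.0, "exponential") == pytest.approx(math.exp(-1))
        assert conductance(5.0, 5.0, "rational") == pytest.approx(0.5)

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            conductance(1.0, 0.0)


class TestDiffusion:
    def test_constant_fixed_point(self):
        img = ImageGrid(np.full((6, 6), 50.0))
        for fn in (gradient_anisotropic_diffusion, curvature_anisotropic_diffusion):
            out = fn(img, DiffusionParams(conductance=10.0, iterations=8))
            np.testing.assert_allclose(out.values, 50.0, atol=1e-9)

    def test_zero_iterations_identity(self):
        img = random_image(4, (5, 5))
        out = gradient_anisotropic_diffusion(img, DiffusionParams(iterations=0))
        np.testing.assert_array_equal(out.values, img.values)

    @pytest.mark.parametrize("form", ["exponential", "rational"])
    def test_gad_matches_naive_reevaluation(self, form):
        img = random_image(7, (5, 5))
        params = DiffusionParams(conductance=10.0, iterations=3, time_step=0.25, form=form)
        mine = gradient_anisotropic_diffusion(img, params).values[:, :, 0]
        ref = img.values[:, :, 0].copy()
        for _ in range(params.iterations):
            ref = naive_gad_step(ref, 10.0, 0.25, form)
        np.testing.assert_allclose(mine, ref, rtol=1e-12)

    def test_cad_matches_naive_reevaluation(self):
        img = random_image(9, (5, 5))
        params = DiffusionParams(conductance=2.0, iterations=2, time_step=0.2)
        mine = curvature_anisotropic_diffusion(img, params).values[:, :, 0]
        ref = img.values[:, :, 0].copy()
        for _ in range(2):
            ref = naive_cad_step(ref, 2.0, 0.2, "exponential")
        np.testing.assert_allclose(mine, ref, rtol=1e-10, atol=1e-10)

    def test_cad_ramp_interior_unchanged(self):
        """A linear ramp has zero level-set curvature: no interior flow."""
        ramp = ImageGrid(np.tile(np.arange(10.0) * 10, (8, 1)))
        out = curvature_anisotropic_diffusion(ramp, DiffusionParams(conductance=5.0, iterations=4))
        np.testing.assert_allclose(out.values[2:-2, 2:-2], ramp.values[2:-2, 2:-2], atol=1e-8)

    def test_gad_extremum_principle(self):
        """Explicit Perona-Malik at tau <= 0.25 never expands the value range."""
        for seed in range(20):
            img = random_image(seed, (8, 8))
            out = gradient_anisotropic_diffusion(img, DiffusionParams(conductance=8.0, iterations=10))
            assert out.values.min() >= img.values.min() - 1e-9
            assert out.values.max() <= img.values.max() + 1e-9


class TestBilateral:
    def test_constant_fixed_point(self):
        img = ImageGrid(np.full((5, 7), 123.0))
        out = bilateral_filter(img, BilateralParams(size=5, sigma_d=2.0, sigma_c=10.0))
        np.testing.assert_allclose(out.values, 123.0, atol=1e-9)

    def test_huge_range_sigma_is_gaussian_blur(self):
        from scipy import ndimage

        img = random_image(3, (15, 15))
        s, sd = 9, 1.5
        out = bilateral_filter(img, BilateralParams(size=s, sigma_d=sd, sigma_c=1e9))
        ref = ndimage.gaussian_filter(img.values[:, :, 0], sigma=sd, truncate=(s // 2) / sd, mode="constant")
        norm = ndimage.gaussian_filter(np.ones_like(ref), sigma=sd, truncate=(s // 2) / sd, mode="constant")
        np.testing.assert_allclose(out.values[4:-4, 4:-4, 0], (ref / norm)[4:-4, 4:-4], rtol=1e-6)

    def test_3x3_window_direct_evaluation(self):
        vals = np.array([[10.0, 20.0, 30.0], [40.0, 50.0, 60.0], [70.0, 80.0, 90.0]])
        sd, sc = 1.0, 25.0
        num = den = 0.0
        for y in range(3):
            for x in range(3):
                w = math.exp(-((x - 1) ** 2 + (y - 1) ** 2) / (2 * sd * sd)) * math.exp(
                    -((vals[y, x] - 50.0) ** 2) / (2 * sc * sc)
                )
                num += w * vals[y, x]
                den += w
        out = bilateral_filter(ImageGrid(vals), BilateralParams(size=3, sigma_d=sd, sigma_c=sc))
        assert out.values[1, 1, 0] == pytest.approx(num / den, rel=1e-12)

    def test_output_within_window_bounds(self):
        img = random_image(17, (10, 10))
        out = bilateral_filter(img, BilateralParams(size=5, sigma_d=2.0, sigma_c=40.0))
        assert out.values.min() >= img.values.min() - 1e-9
        assert out.values.max() <= img.values.max() + 1e-9


class TestRansacArithmetic:
    @pytest.mark.parametrize("d,expected", [(0, 1), (1, 3), (2, 6)])
    def test_min_sample_size(self, d, expected):
        assert min_sample_size(d) == expected

    @pytest.mark.parametrize("sm,expected", [(3, 35), (6, 293)])
    def test_iteration_counts(self, sm, expected):
        """ceil(ln(1-p)/ln(1-(1-eps)^sm)) at p=0.99, eps=0.5."""
        assert ransac_iterations(0.99, 0.5, sm) == expected

    def test_no_outliers_one_draw(self):
        assert ransac_iterations(0.99, 0.0, 3) == 1

    def test_degenerate_arguments(self):
        with pytest.raises(ValueError):
            ransac_iterations(1.5, 0.5, 3)


class TestPolynomialFit:
    def test_exact_plane_interpolation(self):
        samples = np.array([[0.0, 0.0, 5.0], [1.0, 0.0, 7.0], [0.0, 1.0, 8.0]])
        beta = fit_polynomial_window(samples, 1)
        np.testing.assert_allclose(beta, [5.0, 2.0, 3.0], atol=1e-9)

    def test_constant_samples(self):
        samples = np.column_stack([np.arange(4.0), np.arange(4.0) ** 2 % 3, np.full(4, 9.0)])
        beta = fit_polynomial_window(samples, 1)
        np.testing.assert_allclose(beta, [9.0, 0.0, 0.0], atol=1e-9)

    def test_overdetermined_matches_normal_equations(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(-2, 2, (20, 2))
        vals = 1.0 + 0.5 * xy[:, 0] - 2.0 * xy[:, 1] + rng.normal(0, 0.1, 20)
        beta = fit_polynomial_window(np.column_stack([xy, vals]), 1)
        A = np.column_stack([np.ones(20), xy[:, 0], xy[:, 1]])
        ref = np.linalg.solve(A.T @ A, A.T @ vals)
        np.testing.assert_allclose(beta, ref, rtol=1e-9)

    def test_collinear_minimal_sample_raises(self):
        samples = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 2.0], [2.0, 0.0, 3.0]])
        with pytest.raises(SingularFitError):
            fit_polynomial_window(samples, 1)


def grid_positions(n):
    half = n // 2
    xs, ys = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1))
    return np.column_stack([xs.ravel(), ys.ravel()])


class TestLmsRansac:
    def test_exact_plane_zero_median(self):
        pos = grid_positions(3)
        vals = 5.0 + 2.0 * pos[:, 0] + 3.0 * pos[:, 1]
        fit = lms_ransac(pos, vals, LmsParams(size=3, degree=1))
        assert fit.dmed == 0.0
        np.testing.assert_allclose(fit.beta, [5.0, 2.0, 3.0], atol=1e-9)

    def test_plane_with_forty_percent_outliers(self):
        pos = grid_positions(3)
        vals = (5.0 + 2.0 * pos[:, 0] + 3.0 * pos[:, 1]).astype(float)
        vals[[0, 2, 5]] += 1000.0
        fit = lms_ransac(pos, vals, LmsParams(size=3, degree=1))
        assert fit.dmed == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(fit.beta, [5.0, 2.0, 3.0], atol=1e-6)

    def test_5x5_matches_exhaustive_oracle(self):
        """Sampled RANSAC's winner can never beat, and here equals, the
        exhaustive minimum over all minimal samples."""
        rng = np.random.default_rng(42)
        pos = grid_positions(5)
        vals = 2.0 - 1.5 * pos[:, 0] + 0.5 * pos[:, 1]
        bad = rng.choice(25, size=7, replace=False)
        vals = vals.astype(float)
        vals[bad] += rng.uniform(200, 500, 7)
        fit = lms_ransac(pos, vals, LmsParams(size=5, degree=1, seed=3))
        # oracle: exhaustive over all C(25,3) non-collinear triples
        import itertools

        A = np.column_stack([np.ones(25), pos[:, 0], pos[:, 1]])
        best = np.inf
        for idx in itertools.combinations(range(25), 3):
            As = A[list(idx)]
            if abs(np.linalg.det(As)) < 1e-12:
                continue
            beta = np.linalg.solve(As, vals[list(idx)])
            r2 = np.sort(np.delete((vals - A @ beta) ** 2, list(idx)))
            best = min(best, r2[(len(r2) - 1) // 2])
        assert fit.dmed == pytest.approx(best, abs=1e-12)


class TestRobustThreshold:
    def test_equal_residuals_zero(self):
        assert robust_threshold(np.full(9, 3.3)) == 0.0

    def test_symmetric_triple(self):
        assert robust_threshold(np.array([-1.0, 0.0, 1.0])) == pytest.approx(1.4826)

    def test_normal_consistency(self):
        rng = np.random.default_rng(0)
        tr = robust_threshold(rng.normal(0, 1, 100_000))
        assert tr == pytest.approx(1.0, rel=0.02)

    def test_classify(self):
        mask = classify_inliers(np.array([0.5, 2.4, 2.6]), 1.0)
        np.testing.assert_array_equal(mask, [True, True, False])
        mask0 = classify_inliers(np.array([0.0, 1e-12]), 0.0)
        np.testing.assert_array_equal(mask0, [True, False])


class TestLmsFilter:
    def test_global_plane_unchanged(self):
        u, v = np.meshgrid(np.arange(12.0), np.arange(10.0))
        img = ImageGrid(2.0 * u + 1.5 * v + 20.0)
        out = lms_filter(img, LmsParams(size=5, degree=1, seed=0))
        np.testing.assert_allclose(out.values, img.values, atol=1e-9)

    def test_salt_pixels_restored(self):
        u, v = np.meshgrid(np.arange(12.0), np.arange(10.0))
        vals = 2.0 * u + 1.5 * v + 20.0
        vals[4, 6] = 255.0
        vals[7, 2] = 0.0
        out = lms_filter(ImageGrid(vals), LmsParams(size=5, degree=1, seed=0))
        assert out.values[4, 6, 0] == pytest.approx(2.0 * 6 + 1.5 * 4 + 20.0, abs=1e-6)
        assert out.values[7, 2, 0] == pytest.approx(2.0 * 2 + 1.5 * 7 + 20.0, abs=1e-6)

    # a 3x3 window with >50% of pixels off any consistent surface, built so
    # the winning model's robust threshold rejects every non-sample pixel
    FALLBACK_WINDOW = np.array(
        [0.0, 50.19, -36.8507, 45.4115, 0.0, 59.7035, 45.4115, 45.4115, 0.0]
    )

    def test_sparse_inliers_fall_back_to_median(self):
        """When the inlier count is <= the minimal sample size, the center
        pixel becomes the window median."""
        vals = self.FALLBACK_WINDOW
        params = LmsParams(size=3, degree=1, seed=0)
        fit = lms_ransac(grid_positions(3), vals, params)
        tr = robust_threshold(fit.residuals[~fit.sample_mask])
        keep = classify_inliers(fit.residuals, tr) | fit.sample_mask
        assert keep.sum() <= min_sample_size(1)  # the fallback is reached
        out = lms_filter(ImageGrid(vals.reshape(3, 3)), params)
        assert out.values[1, 1, 0] == pytest.approx(np.median(vals))

    def test_deterministic_given_seed(self):
        img = random_image(5, (9, 9))
        a = lms_filter(img, LmsParams(size=5, degree=1, seed=7))
        b = lms_filter(img, LmsParams(size=5, degree=1, seed=7))
        np.testing.assert_array_equal(a.values, b.values)
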