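"""Geometric moments, the moment convolution theorem and moment estimators."""

import numpy as np
import pytest
from scipy.signal import convolve2d

from usblur.exceptions import (DegenerateImageError, InconsistentMomentsError,
                               NoBlurDetectedError, ParameterError)
from usblur.moments import (MomentTable, convolve_moments, deconvolve_moments,
                            estimate_angle_moments, estimate_length_moments,
                            geometric_moments, invariant_set, psf_moment_table,
                            psf_moments_closed_form)
from usblur.psf import MotionBlurParams, make_motion_psf


def brute_force_moments(image, max_order):
    """Independent oracle: explicit double loop over pixels."""
    values = {}
    h, w = image.shape
    for p in range(max_order + 1):
        for q in range(max_order + 1 - p):
            acc = 0.0
            for y in range(h):
                for x in range(w):
                    acc += image[y, x] * x**p * y**q
            values[(p, q)] = acc
    return values


class TestGeometricMoments:
    def test_point_mass(self):
        img = np.zeros((12, 12))
        img[5, 9] = 1.0  # (x0, y0) = (9, 5)
        tab = geometric_moments(img, 3, "raw")
        for (p, q), v in tab.values.items():
            assert v == pytest.approx(9**p * 5**q)

    def test_matches_brute_force(self, rng):
        img = rng.uniform(size=(16, 16))
        tab = geometric_moments(img, 4, "raw")
        oracle = brute_force_moments(img, 4)
        for key, v in oracle.items():
            assert tab.m(*key) == pytest.approx(v, rel=1e-10)

    def test_central_translation_invariance(self, rng):
        img = np.zeros((40, 40))
        img[8:20, 5:17] = rng.uniform(size=(12, 12))
        shifted = np.roll(img, (7, 11), axis=(0, 1))
        a = geometric_moments(img, 4, "central")
        b = geometric_moments(shifted, 4, "central")
        for key in a.values:
            assert a.m(*key) == pytest.approx(b.m(*key), abs=1e-9 * max(1, abs(a.m(*key))))

    def test_all_zero_central_degenerate(self):
        with pytest.raises(DegenerateImageError):
            geometric_moments(np.zeros((8, 8)), 2, "central")

    def test_bad_origin_rejected(self):
        with pytest.raises(ParameterError):
            geometric_moments(np.ones((8, 8)), 2, "weird")


class TestClosedFormPSFMoments:
    def test_zeroth_is_one(self):
        assert psf_moments_closed_form(MotionBlurParams(33, 71), 0, 0) == 1.0

    @pytest.mark.parametrize("p,q", [(1, 0), (0, 1), (3, 0), (2, 1)])
    def test_odd_orders_vanish(self, p, q):
        assert psf_moments_closed_form(MotionBlurParams(10, 30), p, q) == 0.0

    def test_known_value_L2_horizontal(self):
        # (L/2)^2 cos^2(0) / 3 = 1/3
        assert psf_moments_closed_form(MotionBlurParams(2, 0), 2, 0) == pytest.approx(1 / 3)

    def test_matches_numeric_integration(self):
        """Cross-check against numerical integration of the line measure."""
        L, theta = 14, 52
        t = np.linspace(-L / 2, L / 2, 200001)
        c, s = np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))
        for p, q in [(2, 0), (0, 2), (1, 1), (4, 0), (2, 2)]:
            numeric = np.trapezoid((t * c) ** p * (t * s) ** q, t) / L
            assert psf_moments_closed_form(MotionBlurParams(L, theta), p, q) == \
                pytest.approx(numeric, rel=1e-6)

    @pytest.mark.parametrize("L", [15, 20, 30, 60])
    @pytest.mark.parametrize("theta", [0, 30, 45, 85])
    def test_matches_subpixel_kernel_moments(self, L, theta):
        """Closed form vs numerical kernel moments: <=2% of the order's
        natural scale (L/2)^(p+q)/(p+q+1) for p+q <= 4, L >= 15.

        The discrete kernel carries the pixel footprint (~1/6 px^2 across
        the line, ~1/12 along it), an O(1/L^2) bias relative to that scale,
        so the continuous closed form is only reached asymptotically."""
        k = make_motion_psf(MotionBlurParams(L, theta))
        c = (k.shape[0] - 1) / 2
        ys, xs = np.mgrid[0:k.shape[0], 0:k.shape[1]]
        x, y = xs - c, ys - c
        for p, q in [(2, 0), (0, 2), (1, 1), (4, 0), (0, 4), (2, 2)]:
            numeric = float((k.weights * x**p * y**q).sum())
            closed = psf_moments_closed_form(MotionBlurParams(L, theta), p, q)
            scale = (L / 2) ** (p + q) / (p + q + 1)
            assert abs(numeric - closed) <= 0.02 * scale


class TestConvolutionTheorem:
    def test_identity_kernel(self, rng):
        f = geometric_moments(rng.uniform(size=(9, 9)), 4, "raw")
        ident = MomentTable({k: 1.0 if k == (0, 0) else 0.0 for k in f.values}, 4)
        out = convolve_moments(f, ident)
        for key in f.values:
            assert out.m(*key) == pytest.approx(f.m(*key))

    def test_mass_preserved(self, rng):
        f = geometric_moments(rng.uniform(size=(9, 9)), 4, "raw")
        h = psf_moment_table(MotionBlurParams(5, 30), 4)
        assert convolve_moments(f, h).m(0, 0) == pytest.approx(f.m(0, 0))

    def test_matches_explicit_convolution(self, rng):
        """Predicted moments equal moments of the convolved image to 1e-8."""
        f_img = rng.uniform(size=(8, 8))
        h_img = rng.uniform(size=(3, 3))
        h_img /= h_img.sum()
        g_img = convolve2d(f_img, h_img, mode="full")
        f_tab = geometric_moments(f_img, 4, "raw")
        # kernel moments about its center pixel (1, 1)
        ys, xs = np.mgrid[0:3, 0:3]
        h_tab = MomentTable(
            {(p, q): float((h_img * (xs - 1) ** p * (ys - 1) ** q).sum())
             for p in range(5) for q in range(5 - p)}, 4)
        predicted = convolve_moments(f_tab, h_tab)
        # full convolution shifts the origin by the kernel center offset
        xs_off = np.arange(g_img.shape[1]) - 1.0
        ys_off = np.arange(g_img.shape[0]) - 1.0
        xp = np.vander(xs_off, 5, increasing=True).T
        yq = np.vander(ys_off, 5, increasing=True).T
        grid = yq @ g_img @ xp.T
        for (p, q) in predicted.values:
            assert predicted.m(p, q) == pytest.approx(float(grid[q, p]), rel=1e-8)

    def test_deconvolve_inverts(self, rng):
        f = geometric_moments(rng.uniform(size=(10, 10)), 4, "raw")
        h = psf_moment_table(MotionBlurParams(9, 40), 4)
        g = convolve_moments(f, h)
        back = deconvolve_moments(g, h)
        for key in f.values:
            assert back.m(*key) == pytest.approx(f.m(*key), rel=1e-10)

    def test_order_mismatch_rejected(self, rng):
        f = geometric_moments(rng.uniform(size=(8, 8)), 4, "raw")
        h = psf_moment_table(MotionBlurParams(5, 0), 2)
        with pytest.raises(ParameterError):
            convolve_moments(f, h)


class TestSecondOrderRelations:
    def test_variance_excess_identity(self, blur_pair):
        """mu20(g) - mu20(f) ~ (L^2/12) cos^2(theta) m00 within 5%."""
        L, theta = 30, 60
        clean, blurred = blur_pair(L, theta)
        f = geometric_moments(clean, 2, "central")
        g = geometric_moments(blurred, 2, "central")
        c, s = np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))
        for key, factor in [((2, 0), c * c), ((0, 2), s * s), ((1, 1), c * s)]:
            expected = L**2 / 12 * factor * f.m(0, 0)
            assert g.m(*key) - f.m(*key) == pytest.approx(expected, rel=0.05)


class TestEstimators:
    def test_equal_differences_is_45(self):
        f = MomentTable({(0, 0): 1.0, (1, 0): 0, (0, 1): 0, (2, 0): 5.0,
                         (0, 2): 5.0, (1, 1): 0}, 2, "central")
        g = MomentTable({(0, 0): 1.0, (1, 0): 0, (0, 1): 0, (2, 0): 8.0,
                         (0, 2): 8.0, (1, 1): 0}, 2, "central")
        assert estimate_angle_moments(g, f) == pytest.approx(45.0)

    def test_zero_d02_is_horizontal(self):
        f = MomentTable({(0, 0): 1.0, (1, 0): 0, (0, 1): 0, (2, 0): 5.0,
                         (0, 2): 5.0, (1, 1): 0}, 2, "central")
        g = MomentTable({(0, 0): 1.0, (1, 0): 0, (0, 1): 0, (2, 0): 9.0,
                         (0, 2): 5.0, (1, 1): 0}, 2, "central")
        assert estimate_angle_moments(g, f) == pytest.approx(0.0)

    def test_no_blur_raises(self, phantom):
        f = geometric_moments(phantom, 2, "central")
        with pytest.raises(NoBlurDetectedError):
            estimate_angle_moments(f, f)
        with pytest.raises(NoBlurDetectedError):
            estimate_length_moments(f, f)

    def test_inconsistent_moments_raise(self):
        f = MomentTable({(0, 0): 1.0, (1, 0): 0, (0, 1): 0, (2, 0): 5.0,
                         (0, 2): 5.0, (1, 1): 0}, 2, "central")
        g = MomentTable({(0, 0): 1.0, (1, 0): 0, (0, 1): 0, (2, 0): 9.0,
                         (0, 2): 2.0, (1, 1): 0}, 2, "central")
        with pytest.raises(InconsistentMomentsError):
            estimate_angle_moments(g, f)

    def test_algebraic_roundtrip_exact(self, phantom):
        """Moments synthesized through the convolution theorem + closed-form
        PSF moments recover (L=40, theta=45) to 1e-6."""
        f = geometric_moments(phantom, 4, "central")
        h = psf_moment_table(MotionBlurParams(40, 45), 4)
        g = convolve_moments(f, h)
        assert estimate_angle_moments(g, f) == pytest.approx(45.0, abs=1e-6)
        assert estimate_length_moments(g, f) == pytest.approx(40.0, abs=1e-6)

    def test_simulation_recovery(self, blur_pair):
        """Pixel-level blur at (L=30, theta=60): within 2 deg / 10%."""
        clean, blurred = blur_pair(30, 60)
        f = geometric_moments(clean, 2, "central")
        g = geometric_moments(blurred, 2, "central")
        assert estimate_angle_moments(g, f) == pytest.approx(60.0, abs=2.0)
        assert estimate_length_moments(g, f) == pytest.approx(30.0, rel=0.10)


class TestInvariantSet:
    def test_no_blur_returns_clean_values(self, phantom):
        inv = invariant_set(phantom, phantom)
        f_cen = geometric_moments(phantom, 4, "central")
        f_raw = geometric_moments(phantom, 4, "raw")
        assert inv.values[0] == pytest.approx(f_raw.m(0, 0))
        assert inv.values[1] == pytest.approx(np.hypot(f_raw.m(1, 0), f_raw.m(0, 1)))
        for r in (2, 3, 4):
            expected = np.sqrt(sum(f_cen.m(p, r - p) ** 2 for p in range(r + 1)))
            assert inv.values[r] == pytest.approx(expected)

    def test_first_order_raw_moments_preserved(self, blur_pair):
        clean, blurred = blur_pair(40, 45)
        f = geometric_moments(clean, 1, "raw")
        g = geometric_moments(blurred, 1, "raw")
        for key in [(1, 0), (0, 1)]:
            assert g.m(*key) == pytest.approx(f.m(*key), rel=1e-3)

    def test_stability_across_blur_settings(self, blur_pair, phantom):
        """M_r spread across four (L, theta) settings <= 5% of the mean."""
        settings_grid = [(20, 30), (40, 45), (30, 60), (50, 85)]
        per_order = {r: [] for r in range(5)}
        for L, theta in settings_grid:
            clean, blurred = blur_pair(L, theta)
            inv = invariant_set(clean, blurred)
            for r in range(5):
                per_order[r].append(inv.values[r])
        for r, vals in per_order.items():
            vals = np.asarray(vals)
            assert np.ptp(vals) <= 0.05 * abs(vals.mean())

    def test_shape_mismatch_rejected(self, phantom):
        with pytest.raises(ParameterError):
            invariant_set(phantom, phantom[:-2, :])
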