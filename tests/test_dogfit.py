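"""Constrained DoG parametrization and derived RF metrics."""

import numpy as np
import pytest

from panorf import dogfit
from panorf.dogfit import (DoGFit, Gaussian2D, RF2D, center_surround_pixels,
                           classify_rf_type, compute_r2, extract_rf2d,
                           fit_center_gaussian, fit_dog, fit_dog_1d,
                           gaussian2d, radial_profile, summarize_rf,
                           temporal_dynamics)
from panorf.mapping import SpatiotemporalRF


def render_dog(g1: Gaussian2D, g2: Gaussian2D, shape=(50, 50), px=10.0):
    y = (np.arange(shape[0]) + 0.5) * px
    x = (np.arange(shape[1]) + 0.5) * px
    X, Y = np.meshgrid(x, y)
    return g1(X, Y) + g2(X, Y)


def rf2d_of(values, px=10.0, p_var=None):
    values = np.asarray(values, dtype=float)
    return RF2D(values=values, mask=np.ones(values.shape, bool), px_um=px,
                p_var=p_var or (values.shape[0] // 2, values.shape[1] // 2))


def stack_rf(values, latencies=None):
    values = np.asarray(values, dtype=float)
    L = values.shape[2]
    if latencies is None:
        latencies = np.arange(-2, L - 2) * 0.025
    return SpatiotemporalRF(values=values, latencies=np.asarray(latencies),
                            px_um=10.0)


class TestExtractRF2D:
    def test_single_sample_window_is_tvar_slice(self, rng):
        vals = rng.normal(size=(6, 6, 8)) * 0.01
        vals[3, 3, 5] = 5.0
        rf = stack_rf(vals)
        out = extract_rf2d(rf, half_window=0, corr_threshold=0.0)
        np.testing.assert_allclose(out.values, vals[:, :, 5])

    def test_hand_medians(self):
        vals = np.zeros((3, 3, 5))
        base = np.arange(9.0).reshape(3, 3)
        for t in range(5):
            vals[:, :, t] = base * (t + 1)
        rf = stack_rf(vals)
        rf.p_var, rf.t_var = (2, 2), 2
        out = extract_rf2d(rf, half_window=1, corr_threshold=0.0)
        np.testing.assert_allclose(out.values, base * 3)  # median of 2x,3x,4x

    def test_uncorrelated_pixel_excluded(self, rng):
        vals = np.zeros((5, 5, 40))
        sig = np.sin(np.linspace(0, 6, 40))
        vals[2, 2, :] = 2 * sig
        vals[1, 2, :] = sig
        vals[4, 4, :] = rng.normal(size=40)  # uncorrelated noise pixel
        rf = stack_rf(vals)
        rf.p_var, rf.t_var = (2, 2), int(np.argmax(np.abs(sig)))
        out = extract_rf2d(rf, half_window=1, corr_threshold=0.25)
        assert out.mask[1, 2]
        assert not out.mask[4, 4]
        assert out.values[4, 4] == 0.0


class TestClassify:
    def g1(self, sx=40.0, sy=40.0):
        return Gaussian2D(-1.0, 250, 250, sx, sy, 0.0)

    def test_single_blob_is_overlapping(self):
        g1 = self.g1()
        vals = render_dog(g1, Gaussian2D(1e-6, 250, 250, 80, 80, 0.0))
        assert classify_rf_type(rf2d_of(vals), g1) == "overlapping"

    def test_equal_distant_extrema_separated(self):
        vals = np.zeros((50, 50))
        vals[10, 10] = -1.0
        vals[40, 40] = 1.0
        assert classify_rf_type(rf2d_of(vals), self.g1()) == "separated"

    def test_ratio_exactly_075_at_distance_is_separated(self):
        vals = np.zeros((50, 50))
        vals[5, 5] = -1.0
        vals[45, 45] = 0.75  # ratio == 0.75, distance >> d -> strict <
        assert classify_rf_type(rf2d_of(vals), self.g1()) == "separated"

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            classify_rf_type(rf2d_of(np.ones((10, 10))), self.g1())


class TestCenterFit:
    @pytest.mark.parametrize("A,sx,sy,theta", [
        (-1.0, 60.0, 40.0, 0.5),
        (0.8, 45.0, 45.0, 0.0),
    ])
    def test_recovers_rendered_gaussian(self, A, sx, sy, theta):
        true = Gaussian2D(A, 240.0, 260.0, sx, sy, theta)
        vals = render_dog(true, Gaussian2D(-A * 1e-9, 240, 260, 100, 100, 0))
        g = fit_center_gaussian(rf2d_of(vals))
        assert g.A == pytest.approx(A, rel=0.01)
        assert g.m_x == pytest.approx(240.0, abs=1.0)  # 0.1 px
        assert g.m_y == pytest.approx(260.0, abs=1.0)
        assert g.sigma_x == pytest.approx(sx, rel=0.01)
        assert g.sigma_y == pytest.approx(sy, rel=0.01)

    def test_amplitude_sign_follows_dominant_extremum(self):
        vals = render_dog(Gaussian2D(0.5, 250, 250, 50, 50, 0),
                          Gaussian2D(-0.05, 250, 250, 120, 120, 0))
        assert fit_center_gaussian(rf2d_of(vals)).A > 0

    def test_refitting_own_surface_is_a_fixed_point(self):
        true = Gaussian2D(-1.0, 250, 250, 50, 50, 0.0)
        vals = render_dog(true, Gaussian2D(1e-9, 250, 250, 100, 100, 0))
        g = fit_center_gaussian(rf2d_of(vals))
        y = (np.arange(50) + 0.5) * 10.0
        X, Y = np.meshgrid(y, y)
        g2 = fit_center_gaussian(rf2d_of(g(X, Y)))
        assert g2.sigma_x == pytest.approx(g.sigma_x, rel=1e-3)
        assert g2.m_x == pytest.approx(g.m_x, abs=0.1)


class TestFitDog:
    def test_noiseless_render_and_refit_within_5_percent(self):
        g1 = Gaussian2D(-1.0, 250, 250, 50, 45, 0.3)
        g2 = Gaussian2D(0.12, 250, 270, 110, 100, 0.1)
        vals = render_dog(g1, g2)
        rf2d = rf2d_of(vals)
        fit = fit_dog(rf2d, fit_center_gaussian(rf2d))
        assert fit.g2.A == pytest.approx(g2.A, rel=0.05)
        assert fit.g2.m_x == pytest.approx(g2.m_x, abs=0.05 * g2.sigma_x)
        assert fit.g2.m_y == pytest.approx(g2.m_y, abs=0.05 * g2.sigma_y)
        assert fit.g2.sigma_x == pytest.approx(g2.sigma_x, rel=0.05)
        assert fit.g2.sigma_y == pytest.approx(g2.sigma_y, rel=0.05)
        assert fit.g1.A == pytest.approx(g1.A, rel=0.05)

    def test_perfect_fit_r2_one_and_not_flagged(self):
        g1 = Gaussian2D(-1.0, 250, 250, 50, 50, 0.0)
        g2 = Gaussian2D(0.1, 250, 260, 100, 100, 0.0)
        rf2d = rf2d_of(render_dog(g1, g2))
        fit = fit_dog(rf2d, fit_center_gaussian(rf2d))
        assert fit.r2 == pytest.approx(1.0, abs=1e-4)
        assert fit.r2 >= fit.r2_center_only

    def test_opposite_sign_amplitudes_enforced(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            g1 = Gaussian2D(-1.0, 250, 250, 40 + 20 * r.random(), 40, 0.0)
            g2 = Gaussian2D(0.1, 250, 250 + 30 * r.random(), 90, 90, 0.0)
            vals = render_dog(g1, g2) + 0.02 * r.normal(size=(50, 50))
            rf2d = rf2d_of(vals)
            fit = fit_dog(rf2d, fit_center_gaussian(rf2d))
            assert fit.g1.A * fit.g2.A < 0

    def test_overlapping_constraint_respected(self):
        """For overlapping-type fits the surround centre stays within
        d = 2 min(sigma1) of the centre (or the penalty is reported)."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            csig = 40 + 20 * rng.random()
            delta = 60 * (rng.random() - 0.5)
            g1 = Gaussian2D(-1.0, 250, 250, csig, csig, 0.0)
            g2 = Gaussian2D(0.1, 250, 250 + delta, 2.2 * csig, 2.2 * csig, 0.0)
            vals = render_dog(g1, g2) + 0.03 * rng.normal(size=(50, 50))
            rf2d = rf2d_of(vals)
            g1f = fit_center_gaussian(rf2d)
            fit = fit_dog(rf2d, g1f, rf_type="overlapping")
            dist = np.hypot(fit.g2.m_x - fit.g1.m_x, fit.g2.m_y - fit.g1.m_y)
            assert dist <= fit.constraint_d * 1.05 or fit.penalty_active


class TestR2:
    def test_exact_model_gives_one(self, rng):
        vals = rng.normal(size=(6, 6))
        assert compute_r2(rf2d_of(vals), vals) == pytest.approx(1.0)

    def test_mean_model_gives_zero(self, rng):
        vals = rng.normal(size=(6, 6))
        m = np.full_like(vals, vals.mean())
        assert compute_r2(rf2d_of(vals), m) == pytest.approx(0.0, abs=1e-12)

    def test_hand_case(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        m = np.array([[1.0, 2.0], [3.0, 5.0]])
        assert compute_r2(rf2d_of(vals), m) == pytest.approx(0.8)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            compute_r2(rf2d_of(np.ones((4, 4))), np.ones((4, 4)))


class TestSummarize:
    def make_fit(self, g1, g2, rf_type="overlapping"):
        return DoGFit(g1=g1, g2=g2, rf_type=rf_type, r2=1.0,
                      constraint_d=2 * min(g1.sigma_x, g1.sigma_y))

    def test_vertically_symmetric_dog_has_zero_asymmetry(self):
        g1 = Gaussian2D(-1.0, 255, 255, 50, 50, 0.0)
        g2 = Gaussian2D(0.1, 255, 255, 110, 110, 0.0)
        rf2d = rf2d_of(render_dog(g1, g2, shape=(51, 51)))
        s = summarize_rf(self.make_fit(g1, g2), rf2d)
        assert s.vertical_asymmetry == pytest.approx(0.0, abs=1e-6)
        s2 = summarize_rf(self.make_fit(g1, g2), rf2d, va_from_component=False)
        assert s2.vertical_asymmetry == pytest.approx(0.0, abs=1e-6)

    def test_zero_surround_amplitude_gives_zero_relative_surround(self):
        g1 = Gaussian2D(-1.0, 250, 250, 50, 50, 0.0)
        g2 = Gaussian2D(0.0, 250, 250, 100, 100, 0.0)
        rf2d = rf2d_of(render_dog(g1, g2))
        s = summarize_rf(self.make_fit(g1, g2), rf2d, rs_from_component=True)
        assert s.relative_surround == pytest.approx(0.0)

    def test_pixel_memberships_match_exhaustive_quadratic_form(self):
        g1 = Gaussian2D(-1.0, 240, 260, 55, 40, 0.4)
        g2 = Gaussian2D(0.1, 250, 280, 100, 90, 1.1)
        rf2d = rf2d_of(render_dog(g1, g2))
        center, surround = center_surround_pixels(self.make_fit(g1, g2), rf2d)
        X, Y = rf2d.coords()
        for i in range(0, 50, 7):
            for j in range(0, 50, 7):
                q1 = g1.quadratic_form(X[i, j], Y[i, j])
                q2 = g2.quadratic_form(X[i, j], Y[i, j])
                assert center[i, j] == (q1 <= 4.0)
                assert surround[i, j] == ((q2 <= 4.0) and not (q1 <= 4.0))

    def test_hand_rasterized_sums(self):
        # 11x11 grid, px=1: circular G1 (sigma 1.5), G2 (sigma 3)
        g1 = Gaussian2D(-1.0, 5.5, 5.5, 1.5, 1.5, 0.0)
        g2 = Gaussian2D(0.3, 5.5, 5.5, 3.0, 3.0, 0.0)
        vals = render_dog(g1, g2, shape=(11, 11), px=1.0)
        rf2d = rf2d_of(vals, px=1.0)
        s = summarize_rf(self.make_fit(g1, g2), rf2d,
                         va_from_component=False, rs_from_component=False)
        # brute-force per-pixel check
        c_sum = s_sum = 0.0
        n_c = 0
        for i in range(11):
            for j in range(11):
                x, y = j + 0.5, i + 0.5
                r2 = (x - 5.5) ** 2 + (y - 5.5) ** 2
                if r2 <= (2 * 1.5) ** 2:
                    c_sum += vals[i, j]
                    n_c += 1
                elif r2 <= (2 * 3.0) ** 2:
                    s_sum += vals[i, j]
        assert s.n_center_px == n_c
        assert s.relative_surround == pytest.approx(abs(s_sum) / abs(c_sum))
        assert s.center_size_mm2 == pytest.approx(n_c * 1e-6)

    def test_sign_flip_leaves_metrics_unchanged(self):
        g1 = Gaussian2D(-1.0, 250, 250, 50, 45, 0.2)
        g2 = Gaussian2D(0.12, 250, 268, 105, 95, 0.0)
        vals = render_dog(g1, g2)
        rf2d_a, rf2d_b = rf2d_of(vals), rf2d_of(-vals)
        fa = fit_dog(rf2d_a, fit_center_gaussian(rf2d_a))
        fb = fit_dog(rf2d_b, fit_center_gaussian(rf2d_b))
        assert fa.g1.A == pytest.approx(-fb.g1.A, rel=1e-3)
        assert fa.g2.A == pytest.approx(-fb.g2.A, rel=0.02)
        sa, sb = summarize_rf(fa, rf2d_a), summarize_rf(fb, rf2d_b)
        assert sa.relative_surround == pytest.approx(sb.relative_surround, rel=0.02)
        assert sa.vertical_asymmetry == pytest.approx(sb.vertical_asymmetry, abs=0.02)
        assert sa.center_size_mm2 == pytest.approx(sb.center_size_mm2, rel=0.02)

    def test_empty_center_rejected(self):
        g1 = Gaussian2D(-1.0, 5000, 5000, 10, 10, 0.0)  # centre far outside
        g2 = Gaussian2D(0.1, 5000, 5000, 20, 20, 0.0)
        rf2d = rf2d_of(np.random.default_rng(0).normal(size=(20, 20)))
        with pytest.raises(ValueError):
            summarize_rf(self.make_fit(g1, g2), rf2d)


class TestProfilesAndDynamics:
    def test_constant_image_constant_profile(self):
        rf2d = rf2d_of(np.full((21, 21), 2.5))
        _, means = radial_profile(rf2d, (10, 10), ring_width_px=2.0)
        assert np.allclose(means[~np.isnan(means)], 2.5)

    def test_centered_gaussian_profile_decreases(self):
        g = Gaussian2D(1.0, 105, 105, 30, 30, 0.0)
        vals = render_dog(g, Gaussian2D(-1e-12, 105, 105, 60, 60, 0),
                          shape=(21, 21))
        _, means = radial_profile(rf2d_of(vals), (10, 10), ring_width_px=1.0)
        m = means[~np.isnan(means)]
        assert np.all(np.diff(m) < 0)

    def test_ring_membership_matches_distance_scan(self, rng):
        vals = rng.normal(size=(15, 15))
        rf2d = rf2d_of(vals)
        radii, means = radial_profile(rf2d, (7, 7), ring_width_px=1.5)
        for k in range(len(radii)):
            members = []
            for i in range(15):
                for j in range(15):
                    d = np.hypot(i - 7, j - 7)
                    if 1.5 * k <= d < 1.5 * (k + 1):
                        members.append(vals[i, j])
            if members:
                assert means[k] == pytest.approx(np.mean(members))
            else:
                assert np.isnan(means[k])

    def test_temporal_dynamics_hand_means(self):
        vals = np.arange(3 * 3 * 4, dtype=float).reshape(3, 3, 4)
        rf = stack_rf(vals)
        center = np.zeros((3, 3), bool)
        center[1, 1] = True
        surround = np.zeros((3, 3), bool)
        surround[0, 0] = surround[2, 2] = True
        c, s = temporal_dynamics(rf, center, surround)
        np.testing.assert_allclose(c, vals[1, 1])
        np.testing.assert_allclose(s, (vals[0, 0] + vals[2, 2]) / 2)

    def test_single_pixel_center_trace(self, rng):
        vals = rng.normal(size=(4, 4, 6))
        rf = stack_rf(vals)
        center = np.zeros((4, 4), bool)
        center[2, 3] = True
        surround = ~center
        c, _ = temporal_dynamics(rf, center, surround)
        np.testing.assert_array_equal(c, vals[2, 3])

    def test_center_surround_sets_disjoint(self):
        g1 = Gaussian2D(-1.0, 250, 250, 50, 50, 0.0)
        g2 = Gaussian2D(0.1, 250, 260, 100, 100, 0.0)
        rf2d = rf2d_of(render_dog(g1, g2))
        fit = DoGFit(g1=g1, g2=g2, rf_type="overlapping", r2=1.0,
                     constraint_d=100.0)
        center, surround = center_surround_pixels(fit, rf2d)
        assert not np.any(center & surround)


def dog1d(x, ac, as_, lc, ls, sc, ss):
    return (ac * np.exp(-(x - lc) ** 2 / (2 * sc ** 2))
            - as_ * np.exp(-(x - ls) ** 2 / (2 * ss ** 2)))


class TestDog1D:
    x = np.linspace(-25, 25, 101)

    def test_noiseless_recovery_within_5_percent(self):
        true = dict(ac=1.0, as_=0.3, lc=2.0, ls=-1.0, sc=4.0, ss=10.0)
        prof = dog1d(self.x, **true)
        fit = fit_dog_1d(prof, self.x)
        assert fit.amp_center == pytest.approx(1.0, rel=0.05)
        assert fit.amp_surround == pytest.approx(0.3, rel=0.05)
        assert fit.loc_center == pytest.approx(2.0, abs=0.25)
        assert fit.loc_surround == pytest.approx(-1.0, abs=0.6)
        assert fit.sigma_center == pytest.approx(4.0, rel=0.05)
        assert fit.sigma_surround == pytest.approx(10.0, rel=0.05)

    def test_bounds_respected_on_random_profiles(self, rng):
        for _ in range(20):
            prof = dog1d(self.x, 0.5 + rng.random(), 0.5 * rng.random(),
                         10 * (rng.random() - 0.5), 10 * (rng.random() - 0.5),
                         2 + 4 * rng.random(), 8 + 8 * rng.random())
            prof = prof + 0.05 * rng.normal(size=len(self.x))
            if prof.max() <= 0:
                continue
            fit = fit_dog_1d(prof, self.x)
            assert fit.amp_center >= fit.m_peak / 2 - 1e-9
            assert fit.amp_surround >= -1e-12
            assert -20 - 1e-9 <= fit.loc_center <= 20 + 1e-9
            assert -25 - 1e-9 <= fit.loc_surround <= 25 + 1e-9
            assert fit.sigma_center >= fit.w_peak / 4 - 1e-9
            assert fit.sigma_surround >= fit.w_peak - 1e-9

    def test_pure_center_gaussian_puts_surround_at_zero_bound(self):
        prof = dog1d(self.x, 1.0, 0.0, 0.0, 0.0, 5.0, 10.0)
        fit = fit_dog_1d(prof, self.x)
        assert fit.amp_surround == pytest.approx(0.0, abs=1e-3)
        assert fit.constraints_active["amp_surround"]
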