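"""Retina alignment, binning, trend statistics, clustering, tiling and
saccade analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from panorf import population, simulate
from panorf.dogfit import Gaussian2D
from panorf.population import (align_retina, bin_metric_1d, bin_metric_2d,
                               cluster_temporal_rfs, detect_saccades,
                               flip_on_center_rfs, ks_dorsoventral,
                               regression_weights, saccade_orientation_tuning,
                               tiling_index)


def cell_table(rng, n=50, extent=1000.0):
    x = rng.uniform(-extent, extent, n)
    y = rng.uniform(-extent, extent, n)
    return pd.DataFrame({"cell_id": np.arange(n), "x_um": x, "y_um": y,
                         "metric": rng.normal(size=n),
                         "g1_amp": rng.choice([-1.0, 1.0], n)})


class TestAlignRetina:
    def test_optic_nerve_maps_to_origin(self, rng):
        t = cell_table(rng)
        on = (123.0, -456.0)
        t2 = t.copy()
        t2.loc[0, ["x_um", "y_um"]] = on
        out = align_retina(t2, on, ventral_direction_deg=90.0, side="right")
        assert out.loc[0, "x_um"] == pytest.approx(0.0, abs=1e-9)
        assert out.loc[0, "y_um"] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_preserves_distances(self, rng):
        t = cell_table(rng, n=20)
        out = align_retina(t, (50.0, -20.0), ventral_direction_deg=30.0,
                           side="right")
        for i, j in [(0, 5), (3, 17), (8, 9)]:
            d0 = np.hypot(t.x_um[i] - t.x_um[j], t.y_um[i] - t.y_um[j])
            d1 = np.hypot(out.x_um[i] - out.x_um[j], out.y_um[i] - out.y_um[j])
            assert d1 == pytest.approx(d0, abs=1e-9)

    def test_ventral_direction_maps_to_positive_y(self):
        # a cell sitting in the ventral direction from the optic nerve
        t = pd.DataFrame({"x_um": [100.0], "y_um": [0.0]})
        out = align_retina(t, (0.0, 0.0), ventral_direction_deg=0.0,
                           side="right")
        assert out.y_um[0] == pytest.approx(100.0)
        assert out.x_um[0] == pytest.approx(0.0, abs=1e-9)

    def test_left_retina_double_mirror_restores(self, rng):
        t = cell_table(rng, n=10)
        once = align_retina(t, (0.0, 0.0), 90.0, side="left")
        twice = once.copy()
        twice["x_um"] = -twice["x_um"]
        np.testing.assert_allclose(twice["x_um"], t["x_um"], atol=1e-9)

    def test_rf_stack_rotated_consistently(self):
        t = pd.DataFrame({"x_um": [0.0], "y_um": [0.0]})
        rf = np.zeros((5, 5))
        rf[0, 2] = 1.0  # mass at the top
        # ventral at 0 deg means the frame rotates by 90 deg
        _, stacks = align_retina(t, (0, 0), 0.0, side="right", rf_stacks=[rf])
        assert stacks[0].sum() == pytest.approx(1.0)
        assert stacks[0][0, 2] != 1.0  # moved


class TestFlipOnCenter:
    def test_off_cells_unchanged_on_cells_flipped(self, rng):
        t = cell_table(rng, n=30)
        t["g2_amp"] = -t["g1_amp"] * 0.2
        maps = [np.full((3, 3), a) for a in t["g1_amp"]]
        out, flipped_maps = flip_on_center_rfs(t, maps)
        assert (out["g1_amp"] <= 0).all()
        for m in flipped_maps:
            assert m[0, 0] <= 0

    def test_pooled_mean_map_has_negative_center(self, rng):
        # mixed ON/OFF Gaussian bumps cancel without the flip
        maps, amps = [], rng.choice([-1.0, 1.0], 40)
        y, x = np.mgrid[:9, :9]
        bump = np.exp(-((x - 4) ** 2 + (y - 4) ** 2) / 4.0)
        maps = [a * bump for a in amps]
        t = pd.DataFrame({"g1_amp": amps})
        _, flipped = flip_on_center_rfs(t, maps)
        pooled = np.mean(flipped, axis=0)
        assert pooled[4, 4] < -0.9
        assert abs(np.mean(maps, axis=0)[4, 4]) < 0.5


class TestBinning:
    def test_2d_min_count_rule(self):
        t = pd.DataFrame({"x_um": [10.0] * 4, "y_um": [10.0] * 4,
                          "metric": [1.0] * 4})
        bm = bin_metric_2d(t, "metric", bin_um=50.0, min_count=5)
        assert np.all(np.isnan(bm.mean))
        bm2 = bin_metric_2d(t, "metric", bin_um=50.0, min_count=4)
        assert np.nansum(bm2.mean) == pytest.approx(1.0)

    def test_2d_single_bin_equals_global_mean(self, rng):
        t = cell_table(rng, n=30, extent=20.0)
        bm = bin_metric_2d(t, "metric", bin_um=3000.0, min_count=5)
        assert np.nanmax(bm.mean) == pytest.approx(t["metric"].mean())

    def test_2d_matches_groupby_oracle(self, rng):
        t = cell_table(rng, n=50)
        bm = bin_metric_2d(t, "metric", bin_um=500.0, min_count=1)
        edges = bm.bin_edges[0]
        gx = np.digitize(t["x_um"], edges) - 1
        gy = np.digitize(t["y_um"], edges) - 1
        grouped = t.groupby([gx, gy])["metric"].mean()
        for (i, j), v in grouped.items():
            assert bm.mean[i, j] == pytest.approx(v)

    def test_1d_uniform_metric(self, rng):
        t = cell_table(rng, n=40)
        t["metric"] = 3.14
        bm = bin_metric_1d(t, "metric", n_bins=6)
        assert len(bm.mean) == 6
        assert np.allclose(bm.mean[~np.isnan(bm.mean)], 3.14)

    def test_1d_coordinate_metric_matches_groupby(self, rng):
        t = cell_table(rng, n=60)
        t["metric"] = t["y_um"]
        bm = bin_metric_1d(t, "metric", axis="y_um", n_bins=6)
        lo, hi = t["y_um"].min(), t["y_um"].max()
        edges = np.linspace(lo, hi, 7)
        idx = np.clip(np.searchsorted(edges, t["y_um"], side="right") - 1, 0, 5)
        for b in range(6):
            sel = t["y_um"][idx == b]
            if len(sel):
                assert bm.mean[b] == pytest.approx(sel.mean())

    def test_1d_single_bin(self, rng):
        t = cell_table(rng, n=10)
        bm = bin_metric_1d(t, "metric", n_bins=1)
        assert bm.mean[0] == pytest.approx(t["metric"].mean())


class TestKS:
    def test_identical_samples_zero(self):
        d, _ = ks_dorsoventral(np.arange(10.0), np.arange(10.0))
        assert d == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        d, p = ks_dorsoventral(np.arange(10.0), np.arange(100.0, 110.0))
        assert d == pytest.approx(1.0)
        assert p < 1e-4

    def test_interleaved_third(self):
        d, _ = ks_dorsoventral(np.array([1.0, 2, 3]), np.array([1.5, 2.5, 3.5]))
        # brute-force ECDF sweep oracle
        xs = np.array([1.0, 2, 3, 1.5, 2.5, 3.5])
        gaps = [abs(np.mean(np.array([1.0, 2, 3]) <= x)
                    - np.mean(np.array([1.5, 2.5, 3.5]) <= x)) for x in xs]
        assert d == pytest.approx(max(gaps)) == pytest.approx(1.0 / 3.0)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            ks_dorsoventral(np.array([1.0]), np.arange(5.0))


class TestRegression:
    def test_constant_metric_zero_weights(self, rng):
        t = cell_table(rng, n=30)
        t["metric"] = 2.0
        be, ba = regression_weights(t, "metric")
        assert be == pytest.approx(0.0, abs=1e-10)
        assert ba == pytest.approx(0.0, abs=1e-10)

    def test_pure_elevation_gradient(self, rng):
        t = cell_table(rng, n=200)
        y = t["y_um"].to_numpy()
        t["metric"] = 2.0 * (y - y.mean()) / y.std()
        be, ba = regression_weights(t, "metric")
        assert be == pytest.approx(2.0, abs=0.05)
        assert abs(ba) < 0.05


class TestClustering:
    def make_families(self, rng, n_per=100, L=40):
        t = np.linspace(0, 1, L)
        kernels = [np.sin(2 * np.pi * t), np.exp(-t / 0.2) - 0.5,
                   np.cos(4 * np.pi * t) * t]
        X, labels = [], []
        for k, ker in enumerate(kernels):
            for _ in range(n_per):
                X.append(ker + 0.08 * rng.normal(size=L))
                labels.append(k)
        return np.array(X), np.array(labels)

    def test_three_families_recovered(self, rng):
        X, labels = self.make_families(rng)
        res = cluster_temporal_rfs(X, pca_dims=10, k_grid=range(1, 8), seed=0)
        assert res.chosen_k == 3
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels, res.memberships) >= 0.9

    def test_responsibilities_rows_sum_to_one(self, rng):
        X, _ = self.make_families(rng, n_per=40)
        res = cluster_temporal_rfs(X, k_grid=range(1, 6), seed=1)
        np.testing.assert_allclose(res.responsibilities.sum(axis=1), 1.0,
                                   atol=1e-8)

    def test_same_seed_identical_memberships(self, rng):
        X, _ = self.make_families(rng, n_per=30)
        a = cluster_temporal_rfs(X, k_grid=range(1, 6), seed=2)
        b = cluster_temporal_rfs(X, k_grid=range(1, 6), seed=2)
        np.testing.assert_array_equal(a.memberships, b.memberships)
        np.testing.assert_allclose(a.bic_curve, b.bic_curve)

    def test_k_exceeding_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_temporal_rfs(rng.normal(size=(5, 10)), k_grid=[10])


def circle(mx, my, r):
    return Gaussian2D(1.0, mx, my, r / 2.0, r / 2.0, 0.0)  # 2 s.d. contour = r


class TestTilingIndex:
    def test_disjoint_ellipses_give_one(self):
        ells = [circle(0, 0, 50), circle(500, 0, 50), circle(0, 500, 50)]
        assert tiling_index(ells, pitch_um=2.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 4])
    def test_identical_ellipses_give_one_over_k(self, k):
        ells = [circle(10, -5, 80)] * k
        assert tiling_index(ells, pitch_um=2.0) == pytest.approx(1.0 / k)

    def test_half_overlap_gives_075(self):
        """Two unit circles overlapping by half their area: TI = 0.75.
        The centre distance for half-area overlap comes from solving the
        lens-area equation independently."""
        r = 100.0

        def lens_minus_half(d):
            return (2 * r * r * np.arccos(d / (2 * r))
                    - (d / 2) * np.sqrt(4 * r * r - d * d) - np.pi * r * r / 2)

        d = brentq(lens_minus_half, 1e-6, 2 * r - 1e-6)
        ti = tiling_index([circle(0, 0, r), circle(d, 0, r)], pitch_um=1.0)
        assert ti == pytest.approx(0.75, abs=0.01)

    def test_raster_converges_when_halving_pitch(self):
        ells = [circle(0, 0, 120), circle(70, 30, 100), circle(-40, 60, 90)]
        t2 = tiling_index(ells, pitch_um=2.0)
        t1 = tiling_index(ells, pitch_um=1.0)
        assert abs(t1 - t2) / t1 <= 0.01

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            tiling_index([])


class TestSaccades:
    def test_drift_only_trace_yields_none(self):
        eye = simulate.simulate_eye_trace(120.0, saccade_rate_hz=0.0, seed=0)
        assert len(detect_saccades(eye)) == 0

    def test_small_jump_rejected_by_amplitude(self):
        n = 500
        az = np.zeros(n)
        az[250:] = 2.0  # 2 deg jump
        eye = simulate.EyeTrace(time=np.arange(n) / 50.0, azimuth=az,
                                elevation=np.zeros(n), true_saccades=[],
                                sample_hz=50.0)
        assert len(detect_saccades(eye)) == 0

    def test_recovery_of_known_saccades(self):
        eye = simulate.simulate_eye_trace(600.0, saccade_rate_hz=0.25,
                                          preferred_orientation_deg=20.0,
                                          seed=3)
        det = detect_saccades(eye)
        true_times = np.array([s[0] for s in eye.true_saccades])
        got = det["time"].to_numpy()
        matched = sum(np.any(np.abs(got - t) < 0.5) for t in true_times)
        recall = matched / len(true_times)
        false_pos = sum(not np.any(np.abs(true_times - g) < 0.5) for g in got)
        assert recall >= 0.95
        assert false_pos <= 0.05 * max(len(got), 1)

    def test_sampling_rate_guard(self):
        eye = simulate.EyeTrace(time=np.arange(10.0), azimuth=np.zeros(10),
                                elevation=np.zeros(10), true_saccades=[],
                                sample_hz=1.0)
        with pytest.raises(ValueError):
            detect_saccades(eye)


class TestOrientationTuning:
    def saccade_frame(self, amps, dirs):
        return pd.DataFrame({"time": np.arange(len(amps), dtype=float),
                             "amplitude_deg": amps, "direction_deg": dirs})

    def test_collinear_mixed_directions_give_unit_tuning(self):
        s = self.saccade_frame([5, 3, 4, 6], [30, 210, 30, 210])
        out = saccade_orientation_tuning(s)
        assert out.tuning == pytest.approx(1.0)
        assert out.preferred_orientation_deg == pytest.approx(30.0)

    def test_fourfold_symmetric_cancels(self):
        s = self.saccade_frame([2, 2, 2, 2], [0, 45, 90, 135])
        out = saccade_orientation_tuning(s)
        assert out.tuning == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_complex_sum(self, rng):
        amps = rng.random(20) + 0.1
        dirs = rng.uniform(0, 360, 20)
        out = saccade_orientation_tuning(self.saccade_frame(amps, dirs))
        z = np.sum(amps * np.exp(2j * np.deg2rad(dirs)))
        assert out.tuning == pytest.approx(abs(z) / amps.sum(), abs=1e-12)
        expected = np.degrees(0.5 * np.angle(z)) % 180.0
        assert out.preferred_orientation_deg == pytest.approx(expected, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            saccade_orientation_tuning(self.saccade_frame([], []))
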