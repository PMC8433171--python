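"""Camera-ground transform, body volumes, KS test, synthetic scenes."""
import math

import numpy as np
import pytest
from scipy import stats

import striderswarm as sw
from striderswarm.field_data import CameraParams, reduce_detections, wave_speed_consistency


@pytest.fixture
def cam() -> CameraParams:
    return CameraParams(tilt=0.9, hfov=1.0, h=1.5, x_cm=1920, y_cm=1080)


class TestCameraParams:
    @pytest.mark.parametrize("kw", [dict(tilt=0.0), dict(tilt=2.0), dict(hfov=0.0),
                                    dict(h=-1.0), dict(x_cm=0), dict(y_cm=2.5)])
    def test_invalid_rejected(self, kw):
        base = dict(tilt=0.9, hfov=1.0, h=1.5, x_cm=1920, y_cm=1080)
        with pytest.raises(ValueError):
            CameraParams(**{**base, **kw})


class TestCameraToField:
    def test_image_center_maps_to_origin(self, cam):
        x_r, y_r = sw.camera_to_field(cam.x_cm / 2, cam.y_cm / 2, cam)
        assert x_r == pytest.approx(0.0, abs=1e-12)
        assert y_r == pytest.approx(0.0, abs=1e-12)

    def test_mirror_symmetry_in_x(self, cam):
        x1, y1 = sw.camera_to_field(1200.0, 700.0, cam)
        x2, y2 = sw.camera_to_field(cam.x_cm - 1200.0, 700.0, cam)
        assert x2 == pytest.approx(-x1, rel=1e-12)
        assert y2 == pytest.approx(y1, rel=1e-12)

    def test_frozen_independent_evaluation(self, cam):
        # expected values computed by high-precision evaluation of the mapping,
        # independent of this implementation
        x_r, y_r = sw.camera_to_field(1200.0, 700.0, cam)
        assert x_r == pytest.approx(0.244915817628484, rel=1e-12)
        assert y_r == pytest.approx(-0.207582032989517, rel=1e-12)

    def test_above_horizon_rejected(self):
        # shallow tilt: top image rows look above the horizon
        cam = CameraParams(tilt=0.1, hfov=1.6, h=1.5, x_cm=1920, y_cm=1080)
        with pytest.raises(ValueError, match="horizon"):
            sw.camera_to_field(960.0, 0.0, cam)


class TestFieldToCamera:
    def test_origin_maps_to_image_center(self, cam):
        x_c, y_c = sw.field_to_camera(0.0, 0.0, cam)
        assert x_c == pytest.approx(cam.x_cm / 2, abs=1e-9)
        assert y_c == pytest.approx(cam.y_cm / 2, abs=1e-9)

    def test_round_trip_on_random_imageable_points(self, cam):
        # 10^3 random pixels -> field -> pixels, agreement to 1e-9 px
        rng = np.random.default_rng(7)
        x_c = rng.uniform(0, cam.x_cm, 1000)
        y_c = rng.uniform(0, cam.y_cm, 1000)
        x_r, y_r = sw.camera_to_field(x_c, y_c, cam)
        x_b, y_b = sw.field_to_camera(x_r, y_r, cam)
        np.testing.assert_allclose(x_b, x_c, atol=1e-9)
        np.testing.assert_allclose(y_b, y_c, atol=1e-9)

    def test_point_behind_horizon_rejected(self, cam):
        # y_r/h + cot(tilt) <= 0 is not imageable
        y_bad = -cam.h / math.tan(cam.tilt) - 0.1
        with pytest.raises(ValueError, match="imageable"):
            sw.field_to_camera(0.0, y_bad, cam)


class TestEllipsoidVolume:
    def test_sphere_case(self):
        d = 1.3
        assert sw.ellipsoid_volume(d, d) == pytest.approx(math.pi * d**3 / 6)

    def test_direct_evaluation(self):
        assert sw.ellipsoid_volume(2.0, 1.0) == pytest.approx(math.pi / 3)

    def test_scaling_cubes(self):
        assert sw.ellipsoid_volume(4.0, 2.0) == pytest.approx(8 * sw.ellipsoid_volume(2.0, 1.0))

    def test_invalid_axes(self):
        with pytest.raises(ValueError):
            sw.ellipsoid_volume(0.0, 1.0)
        with pytest.raises(ValueError):
            sw.ellipsoid_volume(1.0, 2.0)  # width > length


class TestKSTwoSample:
    def test_identical_samples_zero_distance(self):
        d, p = sw.ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_fully_separated_samples(self):
        d, _ = sw.ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_small_sample_brute_force_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])

        def ecdf(s, x):
            return np.mean(s <= x)

        pts = np.concatenate([a, b])
        d_oracle = max(abs(ecdf(a, x) - ecdf(b, x)) for x in pts)
        d, _ = sw.ks_two_sample(a, b)
        assert d == pytest.approx(d_oracle, abs=1e-15)
        assert d == pytest.approx(1.0 / 3.0, abs=1e-15)

    def test_matches_scipy_on_random_samples(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = rng.normal(size=rng.integers(5, 80))
            b = rng.normal(loc=0.3, size=rng.integers(5, 80))
            d, p = sw.ks_two_sample(a, b)
            ref = stats.ks_2samp(a, b, method="asymp")
            assert d == pytest.approx(ref.statistic, abs=1e-12)
            # both are asymptotic approximations; scipy adds a small-sample
            # correction, so agreement is loose on p while exact on D
            assert p == pytest.approx(ref.pvalue, abs=0.1)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sw.ks_two_sample([], [1.0])


class TestSyntheticScene:
    def _truth(self, rng, n=100):
        pos = np.column_stack([rng.uniform(-3, 3, n), rng.uniform(0.5, 8, n)])
        length = rng.uniform(0.01, 0.02, n)
        width = length * 0.4
        return pos, length, width

    def test_noiseless_recovery_to_micro(self, cam):
        rng = np.random.default_rng(3)
        pos, length, width = self._truth(rng)
        table = sw.synthesize_scene(pos, length, width, cam, sigma_px=0.0)
        red = reduce_detections(table, cam)
        np.testing.assert_allclose(red["x_r"], pos[:, 0], atol=1e-6)
        np.testing.assert_allclose(red["y_r"], pos[:, 1], atol=1e-6)
        np.testing.assert_allclose(red["length"], length, rtol=1e-6)
        np.testing.assert_allclose(red["volume"],
                                   sw.ellipsoid_volume(length, width), rtol=1e-5)

    def test_error_grows_with_noise_and_distance(self, cam):
        rng = np.random.default_rng(4)
        pos, length, width = self._truth(rng, n=400)
        errs = {}
        for sigma in (0.5, 4.0):
            e = []
            for seed in range(5):
                table = sw.synthesize_scene(pos, length, width, cam, sigma_px=sigma, seed=seed)
                red = reduce_detections(table, cam)
                e.append(np.hypot(red["x_r"] - pos[:, 0], red["y_r"] - pos[:, 1]).to_numpy())
            errs[sigma] = np.mean(e, axis=0)
        assert errs[4.0].mean() > errs[0.5].mean()
        near = pos[:, 1] < 2.0
        assert errs[4.0][~near].mean() > errs[4.0][near].mean()

    def test_end_to_end_nnd_histograms_agree(self, cam):
        # recovered positions at 1 px noise: NND distributions agree (KS D < 0.1)
        rng = np.random.default_rng(5)
        pos, length, width = self._truth(rng, n=100)
        table = sw.synthesize_scene(pos, length, width, cam, sigma_px=1.0, seed=6)
        red = reduce_detections(table, cam)
        nnd_true = sw.nearest_neighbor_distances(pos)
        nnd_rec = sw.nearest_neighbor_distances(np.column_stack([red["x_r"], red["y_r"]]))
        d, _ = sw.ks_two_sample(nnd_true, nnd_rec)
        assert d < 0.1

    def test_unimageable_truth_rejected(self, cam):
        with pytest.raises(ValueError):
            sw.synthesize_scene(np.array([[0.0, -10.0]]), [0.01], [0.005], cam)

    def test_missing_columns_rejected(self, cam):
        import pandas as pd
        with pytest.raises(ValueError, match="len_px"):
            reduce_detections(pd.DataFrame({"frame": [0], "x_c": [1.0], "y_c": [1.0]}), cam)


class TestWaveSpeedConsistency:
    def test_consistent_calibration_measures_expected_speed(self, cam):
        # synthesize a wavefront moving 0.24 field units/s away from the camera
        y0 = 2.0
        y1 = y0 + 0.24 * 2.0  # 2 s elapsed
        _, yc0 = sw.field_to_camera(0.0, y0, cam)
        _, yc1 = sw.field_to_camera(0.0, y1, cam)
        speed, rel = wave_speed_consistency(yc0, yc1, cam.x_cm / 2, 2.0, cam)
        assert speed == pytest.approx(0.24, rel=1e-9)
        assert rel < 1e-9

    def test_wrong_height_flagged(self, cam):
        y0, y1 = 2.0, 2.0 + 0.24 * 2.0
        _, yc0 = sw.field_to_camera(0.0, y0, cam)
        _, yc1 = sw.field_to_camera(0.0, y1, cam)
        bad = CameraParams(tilt=cam.tilt, hfov=cam.hfov, h=cam.h * 2, x_cm=cam.x_cm, y_cm=cam.y_cm)
        _, rel = wave_speed_consistency(yc0, yc1, cam.x_cm / 2, 2.0, bad)
        assert rel > 0.5
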