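"""Motion correction, DVARS, outlier rule, tSNR and smoothing."""

from dataclasses import replace

import numpy as np
import pytest

import lumbobold as lb
from lumbobold import phantom, preprocess


class TestDvars:
    def test_hand_computed_example(self):
        """2-voxel mask, successive diffs (3, 4) -> sqrt((9+16)/2)."""
        data = np.zeros((2, 1, 1, 2))
        mask = np.ones((2, 1, 1), dtype=bool)
        data[0, 0, 0] = [0, 3]
        data[1, 0, 0] = [0, 4]
        val = preprocess.dvars(data, mask)
        assert val[0] == pytest.approx(3.5355339, abs=1e-6)

    def test_identical_volumes_give_zero(self):
        data = np.ones((3, 3, 2, 5))
        mask = np.ones((3, 3, 2), dtype=bool)
        assert np.allclose(preprocess.dvars(data, mask), 0.0)

    def test_matches_per_voxel_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            data = rng.normal(size=(6, 6, 3, 10))
            mask = rng.random((6, 6, 3)) > 0.4
            got = preprocess.dvars(data, mask)
            # brute-force loop
            vox = [(i, j, k) for i in range(6) for j in range(6)
                   for k in range(3) if mask[i, j, k]]
            expect = []
            for t in range(1, 10):
                acc = [(data[i, j, k, t] - data[i, j, k, t - 1]) ** 2
                       for i, j, k in vox]
                expect.append(np.sqrt(np.mean(acc)))
            assert np.allclose(got, expect, atol=1e-10)

    def test_spike_volume_elevates_adjacent_transitions(self):
        data = np.ones((4, 4, 2, 10))
        data[..., 5] *= 2.0
        mask = np.ones((4, 4, 2), dtype=bool)
        d = preprocess.dvars(data, mask)
        assert d[4] > 0 and d[5] > 0  # transitions into and out of volume 5
        assert np.allclose(np.delete(d, [4, 5]), 0.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            preprocess.dvars(np.ones((2, 2, 2, 3)), np.zeros((2, 2, 2), bool))


class TestOutlierRule:
    def test_constant_dvars_flags_nothing(self):
        report = preprocess.flag_outliers(np.full(20, 3.0))
        assert report.outlier_volumes == ()

    def test_single_extreme_transition(self):
        """Q75/IQR by linear interpolation: only the 100 is flagged."""
        d = np.array([1, 2, 3, 4, 5, 6, 7, 8, 100], dtype=float)
        report = preprocess.flag_outliers(d)
        assert report.threshold == pytest.approx(7 + 1.5 * 4)
        assert report.outlier_volumes == (9,)  # volume after transition 8->9

    def test_matches_boxplot_reference_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            d = rng.gamma(2.0, 1.0, size=rng.integers(10, 60))
            report = preprocess.flag_outliers(d)
            q75 = np.percentile(d, 75)
            q25 = np.percentile(d, 25)
            expected = tuple(int(i) + 1
                             for i in np.flatnonzero(d > q75 + 1.5 * (q75 - q25)))
            assert report.outlier_volumes == expected

    def test_exclusion_rule_at_20_percent(self):
        keep = preprocess.OutlierReport(np.zeros(99), 1.0,
                                        tuple(range(1, 21)), 100)
        drop = preprocess.OutlierReport(np.zeros(99), 1.0,
                                        tuple(range(1, 26)), 100)
        assert preprocess.exclude_run(keep)       # 20 % exactly is kept
        assert not preprocess.exclude_run(drop)   # 25 % is dropped

    def test_first_volume_never_flagged(self):
        d = np.array([100, 1, 1, 1, 1, 1, 1, 1, 1], dtype=float)
        report = preprocess.flag_outliers(d)
        assert 0 not in report.outlier_volumes


class TestCylindricalMask:
    def test_radius_zero_keeps_centerline_only(self):
        line = np.tile([5.0, 5.0], (3, 1))
        m = preprocess.cylindrical_mask(line, (11, 11, 3), (1, 1, 5), 0.0)
        assert m.sum() == 3
        assert m[5, 5, :].all()

    def test_area_matches_pixel_counting_oracle(self):
        line = np.tile([24.0, 24.0], (2, 1))
        m = preprocess.cylindrical_mask(line, (48, 48, 2), (1, 1, 5), 20.0)
        count = sum(
            1 for i in range(48) for j in range(48)
            if (i - 24) ** 2 + (j - 24) ** 2 <= 400
        )
        assert m[:, :, 0].sum() == count
        assert abs(count - np.pi * 400) / (np.pi * 400) < 0.01

    def test_contains_cord(self, small_geom):
        line = preprocess.cord_centerline(small_geom.cord_mask)
        m = preprocess.cylindrical_mask(line, small_geom.grid_shape,
                                        small_geom.voxel_size_mm, 10.0)
        assert np.all(m[small_geom.cord_mask])


def _rest_run(geom, n_volumes=12, noise=None):
    noise = noise or phantom.QUIET
    run, truth = lb.simulate_run(geom, lb.SEQUENCES["iFOV42"], noise=noise,
                                 n_volumes=n_volumes)
    return run, truth


class TestMocoVolume:
    def test_static_run_yields_near_zero_parameters(self, small_geom):
        run, _ = _rest_run(small_geom, 6)
        est, corrected = preprocess.moco_volume(run.data, (1, 1, 5), dof=3)
        assert np.max(np.abs(est.volume_params)) < 0.01
        assert np.allclose(corrected, run.data, atol=1e-3)

    def test_injected_translation_recovered(self, small_geom):
        motion = np.zeros((8, 6))
        motion[5, 1] = 1.0  # +1 mm along y on volume 5
        noise = replace(phantom.QUIET, motion_volume=motion)
        run, _ = _rest_run(small_geom, 8, noise)
        est, corrected = preprocess.moco_volume(run.data, (1, 1, 5), dof=3)
        assert est.volume_params[5, 1] == pytest.approx(1.0, abs=0.2)
        # corrected series is more stable inside the cord
        sd_corr = corrected[small_geom.cord_mask].std(axis=1).mean()
        sd_raw = run.data[small_geom.cord_mask].std(axis=1).mean()
        assert sd_corr <= sd_raw


class TestMocoSlice:
    def test_lambda_zero_equals_raw_estimates(self, small_geom):
        rng = np.random.default_rng(2)
        run, _ = _rest_run(small_geom, 5)
        data = run.data + rng.normal(0, 1.0, run.data.shape)
        line = preprocess.cord_centerline(small_geom.cord_mask)
        cyl = preprocess.cylindrical_mask(line, small_geom.grid_shape,
                                          (1, 1, 5), 12.0)
        est0, _ = preprocess.moco_slice(data, cyl, (1, 1, 5), lam=0.0)
        # raw estimates on covered slices are untouched by lam=0
        est1, _ = preprocess.moco_slice(data, cyl, (1, 1, 5), lam=np.inf)
        covered = np.array([cyl[:, :, z].any()
                            for z in range(small_geom.grid_shape[2])])
        # for the polynomial fit, slice trajectories are linear in z
        for t in range(data.shape[3]):
            for c in range(2):
                vals = est1.slice_params[t, covered, c]
                # second finite differences of a line vanish
                assert np.max(np.abs(np.diff(vals, 2))) < 1e-8

    def test_injected_slice_ramp_recovered(self, small_geom):
        noise = replace(phantom.QUIET, slice_shift_rostral_mm=0.8)
        run, truth = _rest_run(small_geom, 8, noise)
        line = preprocess.cord_centerline(small_geom.cord_mask)
        cyl = preprocess.cylindrical_mask(line, small_geom.grid_shape,
                                          (1, 1, 5), 12.0)
        est, _ = preprocess.moco_slice(run.data, cyl, (1, 1, 5), lam=0.3)
        err = est.slice_params[:, :, 1] - truth.slice_dy_mm
        assert np.median(np.abs(err)) < 0.2


class TestMotionRecovery:
    def test_random_trajectories_recovered(self, small_geom):
        """Median absolute recovery error < 0.2 mm over random in-plane
        trajectories up to 1.5 mm."""
        rng = np.random.default_rng(7)
        errors = []
        for rep in range(10):
            n = 6
            motion = np.zeros((n, 6))
            motion[1:, :2] = rng.uniform(-1.5, 1.5, size=(n - 1, 2))
            noise = replace(phantom.QUIET, motion_volume=motion,
                            thermal_sd=2.0, seed=rep)
            run, truth = _rest_run(small_geom, n, noise)
            est, _ = preprocess.moco_volume(run.data, (1, 1, 5), dof=2)
            err = est.volume_params[:, :2] - truth.motion_volume[:, :2]
            errors.extend(np.abs(err).ravel())
        assert np.median(errors) < 0.2


class TestTsnr:
    def test_matches_direct_computation(self):
        rng = np.random.default_rng(3)
        data = 100.0 + rng.normal(0, 10.0, size=(4, 4, 2, 50))
        mask = np.ones((4, 4, 2), dtype=bool)
        tmap, _ = preprocess.tsnr(data, mask, erode=False)
        # oracle: per-voxel linear detrend then mean/SD
        t = np.arange(50)
        x = np.stack([np.ones(50), t - t.mean()], axis=1)
        for i in range(4):
            for j in range(4):
                y = data[i, j, 0]
                b = np.linalg.lstsq(x, y, rcond=None)[0]
                r = y - x[:, 1] * b[1]
                assert tmap[i, j, 0] == pytest.approx(
                    r.mean() / r.std(ddof=1), rel=1e-10
                )

    def test_pure_trend_reported_missing(self):
        data = np.zeros((2, 2, 1, 20))
        data[...] = np.arange(20) * 2.0
        mask = np.ones((2, 2, 1), dtype=bool)
        tmap, _ = preprocess.tsnr(data, mask, erode=False)
        assert np.all(np.isnan(tmap))


class TestSmooth:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16, 8), 3.0)
        out = preprocess.smooth(img, (1, 1, 5))
        assert np.allclose(out, img, atol=1e-10)

    def test_total_sum_preserved(self):
        rng = np.random.default_rng(4)
        img = np.zeros((30, 30, 12))
        img[10:20, 10:20, 4:8] = rng.random((10, 10, 4))
        out = preprocess.smooth(img, (1, 1, 5))
        assert out.sum() == pytest.approx(img.sum(), rel=1e-3)

    def test_delta_image_fwhm(self):
        """Empirical FWHM of the smoothed delta within 5 % per axis."""
        img = np.zeros((41, 41, 21))
        img[20, 20, 10] = 1.0
        fwhm = (6.0, 4.0, 10.0)
        vs = (1.0, 1.0, 2.0)
        out = preprocess.smooth(img, vs, fwhm)

        def measured_fwhm(profile, spacing):
            half = profile.max() / 2
            above = np.flatnonzero(profile >= half)
            # linear interpolation at the edges
            lo, hi = above[0], above[-1]
            f = lambda a, b: a + (half - profile[a]) / (profile[b] - profile[a]) * (b - a)
            left = f(lo - 1, lo) if lo > 0 else lo
            right = f(hi + 1, hi) if hi < profile.size - 1 else hi
            return (right - left) * spacing

        assert measured_fwhm(out[:, 20, 10], 1.0) == pytest.approx(6.0, rel=0.05)
        assert measured_fwhm(out[20, :, 10], 1.0) == pytest.approx(4.0, rel=0.05)
        assert measured_fwhm(out[20, 20, :], 2.0) == pytest.approx(10.0, rel=0.05)

    def test_rejects_nonpositive_fwhm(self):
        with pytest.raises(ValueError):
            preprocess.smooth(np.ones((4, 4, 2)), (1, 1, 5), (0, 1, 1))
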