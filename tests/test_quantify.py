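"""Atlas sectors, alignment, activity tables, effect size, Dice."""

import numpy as np
import pytest

import lumbobold as lb
from lumbobold import design, inference, phantom, pipeline, quantify


@pytest.fixture(scope="module")
def atlas(geom):
    return quantify.build_atlas(geom)


class TestAtlas:
    def test_quadrants_symmetric_on_symmetric_phantom(self, geom, atlas):
        for z in range(geom.grid_shape[2]):
            rv = atlas.sector_mask("RV")[:, :, z].sum()
            lv = atlas.sector_mask("LV")[:, :, z].sum()
            rd = atlas.sector_mask("RD")[:, :, z].sum()
            ld = atlas.sector_mask("LD")[:, :, z].sum()
            assert rv == lv
            assert rd == ld

    def test_center_gap_belongs_to_no_quadrant(self, geom, atlas):
        code = atlas.sector_of_voxel
        gap_codes = set(
            np.unique(code[atlas.center_row, :, :])
        ) | set(np.unique(code[:, atlas.center_col, :]))
        # only background (0) or MV may appear on the center lines
        assert gap_codes <= {0, quantify.SECTORS.index("MV") + 1}
        for name in ("RV", "RD", "LV", "LD"):
            m = atlas.sector_mask(name)
            assert not m[atlas.center_row, :, :].any()
            assert not m[:, atlas.center_col, :].any()

    def test_sectors_disjoint_and_inside_cord(self, geom, atlas):
        code = atlas.sector_of_voxel
        assert np.all((code == 0) | geom.cord_mask)
        # MV is anterior-midline and contiguous in-plane
        mv = atlas.sector_mask("MV")
        cx, cy = geom.config.center
        xs, ys, _ = np.nonzero(mv)
        assert np.all(ys < cy)

    def test_sector_assignment_matches_per_voxel_rule_oracle(self, geom,
                                                             atlas):
        """Re-derive each voxel's quadrant from its coordinates."""
        code = atlas.sector_of_voxel
        ci, cj = atlas.center_row, atlas.center_col
        mv_code = quantify.SECTORS.index("MV") + 1
        nx, ny, nz = geom.grid_shape
        for z in (geom.tip_slice_index, geom.lse_slice_index, nz - 1):
            for i in range(nx):
                for j in range(ny):
                    got = code[i, j, z]
                    if got == mv_code or got == 0:
                        continue
                    name = quantify.SECTORS[got - 1]
                    assert geom.cord_mask[i, j, z]
                    assert i != ci and j != cj
                    expect = ("R" if i < ci else "L") + (
                        "V" if j < cj else "D")
                    assert name == expect


class TestTwoLandmarkAlign:
    def test_identity_when_landmarks_match(self):
        f = quantify.two_landmark_align(10, 2, 10, 2)
        z = np.arange(15)
        assert np.allclose(f(z), z)

    def test_slope_follows_span_ratio(self):
        f = quantify.two_landmark_align(12, 2, 22, 2)  # span 10 -> 20
        assert f(7) == pytest.approx(12.0)  # midpoint maps to midpoint
        assert f(12) - f(11) == pytest.approx(2.0)

    def test_monotone_increasing(self):
        f = quantify.two_landmark_align(9, 3, 14, 1)
        z = np.linspace(-2, 20, 50)
        assert np.all(np.diff(f(z)) > 0)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(ValueError):
            quantify.two_landmark_align(5, 5, 10, 2)


class TestActivityStats:
    def test_fully_significant_map(self, geom, atlas):
        tmap = np.ones(geom.grid_shape)
        p = np.zeros(geom.grid_shape)
        table = quantify.activity_stats(tmap, p, atlas)
        filled = table.dropna(subset=["mean_t"])
        for a in (0.05, 0.01, 0.001):
            assert np.allclose(filled[f"ratio_p{a}"], 1.0)

    def test_matches_per_voxel_loop_oracle(self, geom, atlas):
        rng = np.random.default_rng(0)
        tmap = rng.normal(size=geom.grid_shape)
        p = rng.random(geom.grid_shape)
        table = quantify.activity_stats(tmap, p, atlas).set_index(
            ["kind", "name"])
        slab = atlas.level_mask(quantify.LEVELS)
        for name in quantify.SECTORS:
            region = atlas.sector_mask(name) & slab
            vals = [tmap[i, j, k] for i, j, k in np.argwhere(region)]
            ps = [p[i, j, k] for i, j, k in np.argwhere(region)]
            row = table.loc[("sector", name)]
            assert row["mean_t"] == pytest.approx(np.mean(vals))
            assert row["ratio_p0.01"] == pytest.approx(
                np.mean([q < 0.01 for q in ps]))

    def test_localized_activation_found_in_rv(self, geom, atlas):
        """Activation confined to RV on mid levels dominates the table."""
        tmap = np.zeros(geom.grid_shape)
        p = np.ones(geom.grid_shape)
        region = atlas.sector_mask("RV") & atlas.level_mask(("L4", "L5"))
        tmap[region] = 5.0
        p[region] = 0.001
        table = quantify.activity_stats(tmap, p, atlas)
        sectors = table[table.kind == "sector"].set_index("name")
        assert sectors["mean_t"].idxmax() == "RV"
        levels = table[table.kind == "level"].dropna(subset=["mean_t"])
        assert levels.set_index("name")["mean_t"].idxmax() in ("L4", "L5")


class TestDice:
    def test_identical_nonempty_maps(self):
        a = np.zeros((4, 4), bool)
        a[:2] = True
        assert quantify.dice(a, a) == 1.0

    def test_disjoint_maps(self):
        a = np.zeros(8, bool)
        b = np.zeros(8, bool)
        a[:4], b[4:] = True, True
        assert quantify.dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros(10, bool)
        b = np.zeros(10, bool)
        a[:4], b[2:6] = True, True
        assert quantify.dice(a, b) == 0.5

    def test_both_empty_defined_as_zero(self):
        assert quantify.dice(np.zeros(5, bool), np.zeros(5, bool)) == 0.0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.random(30) > 0.5
            b = rng.random(30) > 0.5
            d1, d2 = quantify.dice(a, b), quantify.dice(b, a)
            assert d1 == d2
            assert 0.0 <= d1 <= 1.0


class TestSplitHalf:
    def test_identical_halves_give_unit_dice(self):
        rng = np.random.default_rng(2)
        copes = 3.0 + rng.normal(size=(8, 4, 4, 2))
        out = quantify.split_half(copes, copes.copy(),
                                  variance_fwhm_mm=0.0,
                                  tfce_kwargs={"n_steps": 15})
        assert out[0.05] == 1.0

    def test_independent_null_halves_near_zero(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 4, 4, 2))
        b = rng.normal(size=(8, 4, 4, 2))
        out = quantify.split_half(a, b, variance_fwhm_mm=0.0,
                                  tfce_kwargs={"n_steps": 15})
        assert out[0.05] <= 0.2

    def test_threshold_nestedness_on_matched_signal(self):
        rng = np.random.default_rng(4)
        signal = np.zeros((4, 4, 2))
        signal[1:3, 1:3, :] = 2.5
        a = signal[None] + rng.normal(size=(10, 4, 4, 2))
        b = signal[None] + rng.normal(size=(10, 4, 4, 2))
        out = quantify.split_half(a, b, variance_fwhm_mm=0.0,
                                  tfce_kwargs={"n_steps": 15})
        assert out[0.05] >= out[0.001]


class TestFalsePositiveRate:
    def test_zero_map(self, small_geom):
        z = np.zeros(small_geom.grid_shape)
        assert quantify.false_positive_rate(z, small_geom.cord_mask) == 0.0

    def test_gaussian_null_near_nominal(self, small_geom):
        rng = np.random.default_rng(5)
        rates = [
            quantify.false_positive_rate(
                rng.normal(size=small_geom.grid_shape),
                small_geom.cord_mask)
            for _ in range(200)
        ]
        assert np.mean(rates) == pytest.approx(0.01, abs=0.002)


class TestEffectSize:
    def _run_stats(self, geom, seq, paradigm, delta, response="boxcar"):
        act = lb.ActivationSpec(
            target_mask=lb.right_ventral_target(geom), delta_r2star=delta,
            response_model=response,
        )
        n = design.volumes_for_run(paradigm.total_duration_s, seq.tr_ms)
        run, _ = lb.simulate_run(geom, seq, activation=act,
                                 noise=phantom.QUIET, paradigm=paradigm,
                                 n_volumes=n)
        opts = pipeline.RunLevelOptions(
            do_moco=False, do_acompcor=False, do_smooth=False,
            task_model="boxcar",
        )
        return pipeline.process_task_run(run, geom, opts).stats

    def test_null_run_gives_zero(self, small_geom, paradigm10):
        seq = lb.SEQUENCES["iFOV42"]
        stats = self._run_stats(small_geom, seq, paradigm10, 0.0)
        atlas = quantify.build_atlas(small_geom)
        roi = atlas.sector_mask("RV") & small_geom.gm_mask
        pct, _ = quantify.effect_size(stats, roi, paradigm10, seq.tr_ms)
        assert abs(pct) < 1e-6

    def test_monotone_in_delta_r2star(self, small_geom, paradigm10):
        seq = lb.SEQUENCES["iFOV42"]
        atlas = quantify.build_atlas(small_geom)
        roi = atlas.sector_mask("RV") & small_geom.gm_mask
        vals = []
        for delta in (0.05, 0.1377, 0.25):
            stats = self._run_stats(small_geom, seq, paradigm10, delta)
            pct, _ = quantify.effect_size(stats, roi, paradigm10, seq.tr_ms)
            vals.append(pct)
        assert np.all(np.diff(vals) > 0)

    def test_empty_roi_rejected(self, small_geom, paradigm10):
        seq = lb.SEQUENCES["iFOV42"]
        stats = self._run_stats(small_geom, seq, paradigm10, 0.0)
        with pytest.raises(ValueError):
            quantify.effect_size(stats, np.zeros(small_geom.grid_shape, bool),
                                 paradigm10, seq.tr_ms)
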