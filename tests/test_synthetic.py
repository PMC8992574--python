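"""Generator tests: archetype validation, curve anchors, noise, rendering, I/O."""

import numpy as np
import pytest

from graperipe import synthetic
from graperipe.synthetic import (ArchetypeValidationError, ChannelTrajectory,
                                 TrajectoryConfig, VarietyArchetype, default_weeks,
                                 generate_color_series, generate_indicator_series,
                                 noise_free_indicators, render_cluster_image)


def _make_archetype(**overrides):
    base = dict(
        name="test", final_weight=10.0, final_long_diam=30.0, final_horiz_diam=27.0,
        final_compactness=1.5, final_ssc=20.0, final_ta=0.4,
        ta_peak_week=9.0, ta_peak_value=1.0,
        stage_boundary_week=12.0, harvest_week=15.0,
        color={
            "r": ChannelTrajectory("monotone_increasing", 60.0, 180.0),
            "g": ChannelTrajectory("monotone_decreasing", 150.0, 80.0),
            "b": ChannelTrajectory("unimodal", 60.0, 70.0, peak_week=10.0, peak_value=110.0),
        },
    )
    base.update(overrides)
    return VarietyArchetype(**base)


# ---------------------------------------------------------------- validation

class TestValidation:
    def test_unknown_color_mode_rejected(self):
        with pytest.raises(ArchetypeValidationError):
            ChannelTrajectory("wiggly", 0.0, 1.0)

    def test_unimodal_requires_peak(self):
        with pytest.raises(ArchetypeValidationError):
            ChannelTrajectory("unimodal", 0.0, 1.0)

    def test_monotone_direction_enforced(self):
        with pytest.raises(ArchetypeValidationError):
            ChannelTrajectory("monotone_increasing", 100.0, 50.0)
        with pytest.raises(ArchetypeValidationError):
            ChannelTrajectory("monotone_decreasing", 50.0, 100.0)

    def test_boundary_must_precede_harvest(self):
        with pytest.raises(ArchetypeValidationError):
            _make_archetype(stage_boundary_week=16.0)

    def test_compactness_at_least_one(self):
        with pytest.raises(ArchetypeValidationError):
            _make_archetype(final_compactness=0.9)

    def test_acid_peak_exceeds_final(self):
        with pytest.raises(ArchetypeValidationError):
            _make_archetype(ta_peak_value=0.3)

    def test_missing_channel_rejected(self):
        with pytest.raises(ArchetypeValidationError):
            _make_archetype(color={"r": ChannelTrajectory("monotone_increasing", 0, 1)})

    def test_weeks_must_increase(self):
        with pytest.raises(ValueError):
            TrajectoryConfig(weeks=(4.0, 4.0, 5.0))

    def test_noise_sd_bounded(self):
        with pytest.raises(ValueError):
            TrajectoryConfig(weeks=(4.0, 5.0), noise_sd=0.5)

    def test_default_archetypes_valid(self):
        assert set(synthetic.DEFAULT_ARCHETYPES) == {
            "drunk_incense", "muscat_hamburg", "xiang_yue"}


# ------------------------------------------------------------- clean curves

class TestCleanCurves:
    def test_final_values_hit_exactly_at_harvest(self):
        for arch in synthetic.DEFAULT_ARCHETYPES.values():
            curves = noise_free_indicators(arch, [arch.harvest_week])
            assert curves["weight"][0] == pytest.approx(arch.final_weight, abs=1e-9)
            assert curves["long_diam"][0] == pytest.approx(arch.final_long_diam, abs=1e-9)
            assert curves["ssc"][0] == pytest.approx(arch.final_ssc, abs=1e-9)

    def test_acid_reaches_final_at_boundary_then_plateaus(self, di_archetype):
        arch = di_archetype
        weeks = [arch.stage_boundary_week, arch.stage_boundary_week + 1, arch.harvest_week]
        ta = noise_free_indicators(arch, weeks)["titratable_acid"]
        assert np.allclose(ta, arch.final_ta)

    def test_acid_peaks_at_configured_week(self, di_archetype):
        arch = di_archetype
        weeks = np.asarray(default_weeks(arch))
        ta = noise_free_indicators(arch, weeks)["titratable_acid"]
        assert weeks[np.argmax(ta)] == arch.ta_peak_week
        assert ta.max() == pytest.approx(arch.ta_peak_value, abs=1e-9)

    def test_weight_monotone_increasing(self, di_archetype):
        w = noise_free_indicators(di_archetype, default_weeks(di_archetype))["weight"]
        assert np.all(np.diff(w) > 0)

    def test_compactness_decreasing_toward_final(self, di_archetype):
        c = noise_free_indicators(di_archetype, default_weeks(di_archetype))["compactness"]
        assert np.all(np.diff(c) < 0)
        assert c[-1] == pytest.approx(di_archetype.final_compactness, rel=1e-2)

    def test_all_indicators_positive(self):
        for arch in synthetic.DEFAULT_ARCHETYPES.values():
            curves = noise_free_indicators(arch, default_weeks(arch))
            for name, v in curves.items():
                assert np.all(v > 0), name


# ------------------------------------------------------------ noisy series

class TestIndicatorSeries:
    def test_ratio_identity_holds_exactly(self, di_archetype):
        cfg = TrajectoryConfig(weeks=default_weeks(di_archetype), noise_sd=0.05, seed=3)
        s = generate_indicator_series(di_archetype, cfg)
        assert np.array_equal(s.ssc_acid_ratio, s.ssc / s.titratable_acid)

    def test_same_seed_reproduces(self, di_archetype):
        cfg = TrajectoryConfig(weeks=default_weeks(di_archetype), noise_sd=0.05, seed=9)
        a = generate_indicator_series(di_archetype, cfg)
        b = generate_indicator_series(di_archetype, cfg)
        assert np.array_equal(a.weight, b.weight)
        assert np.array_equal(a.ssc, b.ssc)

    def test_different_seed_differs(self, di_archetype):
        weeks = default_weeks(di_archetype)
        a = generate_indicator_series(di_archetype, TrajectoryConfig(weeks, 0.05, 1))
        b = generate_indicator_series(di_archetype, TrajectoryConfig(weeks, 0.05, 2))
        assert not np.array_equal(a.weight, b.weight)

    def test_zero_noise_equals_clean_curves(self, di_archetype, di_clean_series):
        clean = noise_free_indicators(di_archetype, di_clean_series.week)
        assert np.allclose(di_clean_series.weight, clean["weight"])
        assert np.allclose(di_clean_series.titratable_acid, clean["titratable_acid"])

    def test_weeks_outside_window_rejected(self, di_archetype):
        with pytest.raises(ValueError):
            generate_indicator_series(
                di_archetype, TrajectoryConfig(weeks=(3.0, 5.0)))


# ------------------------------------------------------------- color series

class TestColorSeries:
    def test_monotone_channel_is_monotone(self, di_clean_color):
        # drunk_incense R and G are monotone_increasing
        assert np.all(np.diff(di_clean_color.rgb[:, 0]) >= 0)
        assert np.all(np.diff(di_clean_color.rgb[:, 1]) >= 0)

    def test_unimodal_channel_peaks_at_configured_week(self, di_archetype, di_clean_color):
        b = di_clean_color.rgb[:, 2]
        peak_week = di_archetype.color["b"].peak_week
        assert di_clean_color.week[np.argmax(b)] == peak_week

    def test_channel_anchors(self, di_archetype, di_clean_color):
        r = di_archetype.color["r"]
        assert di_clean_color.rgb[0, 0] == pytest.approx(r.start, abs=1e-9)
        assert di_clean_color.rgb[-1, 0] == pytest.approx(r.end, abs=1e-9)

    def test_values_clamped_to_rgb_range(self, di_archetype, di_timeline):
        cfg = TrajectoryConfig(weeks=tuple(float(w) for w in di_timeline.weeks),
                               noise_sd=0.2, seed=4)
        series = generate_color_series(di_archetype, di_timeline, cfg)
        assert np.all(series.rgb >= 0) and np.all(series.rgb <= 255)

    def test_labels_match_timeline(self, di_timeline, di_clean_color):
        assert np.array_equal(di_clean_color.mc, di_timeline.mc)
        assert np.array_equal(di_clean_color.mc_raw, di_timeline.mc_raw)

    def test_uncovered_weeks_rejected(self, di_archetype, di_timeline):
        cfg = TrajectoryConfig(weeks=(4.0, 4.25), noise_sd=0.0, seed=0)
        with pytest.raises(ValueError):
            generate_color_series(di_archetype, di_timeline, cfg)

    def test_color_is_constant_after_full_maturity(self, di_timeline, di_clean_color):
        after = di_clean_color.week >= di_timeline.full_maturity_week
        assert after.sum() >= 2
        assert np.allclose(np.diff(di_clean_color.rgb[after], axis=0), 0.0)


# ---------------------------------------------------------------- rendering

class TestRendering:
    def test_mask_mean_reproduces_mean_rgb(self):
        img = render_cluster_image((120.0, 150.0, 90.0), n_berries=6,
                                   image_size=96, seed=5)
        measured = img.pixels[img.berry_mask].mean(axis=0)
        assert np.allclose(measured, [120.0, 150.0, 90.0], atol=1.0)

    def test_deterministic_given_seed(self):
        a = render_cluster_image((100, 100, 100), 4, image_size=64, seed=1)
        b = render_cluster_image((100, 100, 100), 4, image_size=64, seed=1)
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(a.berry_mask, b.berry_mask)

    def test_background_is_near_white(self):
        img = render_cluster_image((50, 50, 50), 4, image_size=64, seed=2)
        bg = img.pixels[~img.berry_mask]
        assert bg.min() >= 235 and bg.max() <= 250

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            render_cluster_image((100, 100, 100), n_berries=25, image_size=16)

    def test_bad_mean_rgb_rejected(self):
        with pytest.raises(ValueError):
            render_cluster_image((300, 0, 0), 4)


# ----------------------------------------------------------------------- I/O

class TestIO:
    def test_indicator_csv_round_trip(self, di_clean_series, tmp_path):
        p = tmp_path / "ind.csv"
        synthetic.write_indicator_csv(di_clean_series, p)
        back = synthetic.read_indicator_csv(p)
        assert np.allclose(back.week, di_clean_series.week)
        assert np.allclose(back.ssc_acid_ratio, di_clean_series.ssc_acid_ratio)

    def test_color_csv_round_trip_keeps_raw_mc(self, di_clean_color, tmp_path):
        p = tmp_path / "color.csv"
        synthetic.write_color_csv(di_clean_color, p)
        back = synthetic.read_color_csv(p)
        assert np.allclose(back.rgb, di_clean_color.rgb)
        assert np.allclose(back.mc, di_clean_color.mc)
        assert np.allclose(back.mc_raw, di_clean_color.mc_raw)

    def test_png_round_trip_exact(self, tmp_path):
        img = render_cluster_image((90, 120, 60), 4, image_size=48, seed=3)
        p = tmp_path / "img.png"
        synthetic.save_image_png(img, p)
        assert np.array_equal(synthetic.load_image_png(p), img.pixels)

    def test_archetype_yaml_round_trip(self, di_archetype, tmp_path):
        p = tmp_path / "arch.yaml"
        synthetic.archetype_to_yaml(di_archetype, p)
        back = synthetic.archetype_from_yaml(p)
        assert back == di_archetype
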