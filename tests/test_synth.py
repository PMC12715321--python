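"""Generator contracts: cohort sampling, area targeting, artifacts, datasets."""

import numpy as np
import pandas as pd
import pytest

from penstroke.errors import ConfigurationError, GenerationError
from penstroke.metrics import measure_row, sequence_effect
from penstroke.synth import (
    ArtifactParams,
    GeneratorConfig,
    SheetGroundTruth,
    SubjectProfile,
    add_scan_artifacts,
    render_sheet,
    row_area_profile,
    sample_subject_profiles,
    write_dataset,
)


class TestSampleProfiles:
    def test_draws_center_on_group_means(self, default_config):
        """At n=1000 the sample mean lies within 3 SE of the configured mean."""
        profiles = sample_subject_profiles(default_config, {"HS": 1000}, seed=5)
        areas = np.array([p.base_area_mm2 for p in profiles])
        seqs = np.array([p.seq_effect for p in profiles])
        mu_a, sd_a = default_config.group_area_params["HS"]
        mu_s, sd_s = default_config.group_seqeffect_params["HS"]
        assert abs(areas.mean() - mu_a) < 3 * sd_a / np.sqrt(1000)
        assert abs(seqs.mean() - mu_s) < 3 * sd_s / np.sqrt(1000)

    def test_zero_sd_gives_exact_means(self):
        config = GeneratorConfig(
            group_area_params={"HS": (126.72, 0.0)},
            group_seqeffect_params={"HS": (1.05, 0.0)},
        )
        profiles = sample_subject_profiles(config, {"HS": 5}, seed=0)
        assert all(p.base_area_mm2 == 126.72 for p in profiles)
        assert all(p.seq_effect == 1.05 for p in profiles)

    def test_truncation_floor_at_ten_percent_of_mean(self, default_config):
        profiles = sample_subject_profiles(default_config, {"PD_OFF": 2000}, seed=3)
        mu, _ = default_config.group_area_params["PD_OFF"]
        assert min(p.base_area_mm2 for p in profiles) >= 0.1 * mu

    def test_reproducible_from_seed(self, default_config):
        a = sample_subject_profiles(default_config, {"HS": 4, "PD_OFF": 4}, seed=9)
        b = sample_subject_profiles(default_config, {"HS": 4, "PD_OFF": 4}, seed=9)
        assert [(p.subject_id, p.base_area_mm2, p.seq_effect) for p in a] == [
            (p.subject_id, p.base_area_mm2, p.seq_effect) for p in b
        ]

    def test_unknown_group_rejected(self, default_config):
        with pytest.raises(ConfigurationError, match="unknown group"):
            sample_subject_profiles(default_config, {"XX": 3}, seed=0)

    def test_stage_set_iff_pd(self, default_config):
        profiles = sample_subject_profiles(
            default_config, {"HS": 3, "PD_OFF": 4, "PD_mid_OFF": 2}, seed=1
        )
        for p in profiles:
            assert (p.stage != "none") == (p.group == "PD")


class TestRowAreaProfile:
    def test_flat_when_no_sequence_effect(self):
        g = row_area_profile(100.0, 1.0, 10)
        assert np.allclose(g, 100.0)

    def test_last5_first5_ratio_by_construction(self):
        g = row_area_profile(100.0, 0.9, 10)
        assert np.isclose(g[5:].mean() / g[:5].mean(), 0.9)
        assert np.isclose(g[:5].mean(), 100.0)

    @pytest.mark.parametrize("seq", [0.6, 0.92, 1.0, 1.05, 1.4])
    def test_first_half_mean_equals_base(self, seq):
        g = row_area_profile(80.0, seq, 10)
        assert np.isclose(g[:5].mean(), 80.0)


class TestRenderSheet:
    def test_realized_areas_match_targets_within_2pct(self, hs_sheet):
        _, gt = hs_sheet
        realized = np.array(gt.realized_areas_mm2)
        target = np.array(gt.target_areas_mm2)
        assert np.all(np.abs(realized - target) / target <= 0.02)

    def test_boxes_disjoint_and_ordered(self, hs_sheet):
        _, gt = hs_sheet
        for (x0, y0, x1, y1), (nx0, ny0, nx1, ny1) in zip(gt.boxes, gt.boxes[1:]):
            assert y1 <= ny0, "row boxes must be vertically disjoint, top to bottom"

    def test_measurement_round_trip_within_2pct(self, pd_sheet):
        """Re-measuring an artifact-free render recovers every target area."""
        page, gt = pd_sheet
        rows = [
            measure_row(page[y0:y1, x0:x1], gt.calibration, row_index=i + 1)
            for i, (x0, y0, x1, y1) in enumerate(gt.boxes)
        ]
        areas = np.array([r.ink_area_mm2 for r in rows])
        target = np.array(gt.target_areas_mm2)
        assert np.all(np.abs(areas - target) / target <= 0.02)
        assert sequence_effect(rows) == pytest.approx(0.92, abs=0.02)

    def test_ink_monotone_in_base_area(self, default_config):
        counts = []
        for base in (60.0, 90.0, 140.0):
            profile = SubjectProfile("S", "HS", base_area_mm2=base, seq_effect=1.0)
            page, _ = render_sheet(profile, "sentence", default_config, seed=4)
            counts.append(int((page < 128).sum()))
        assert counts[0] < counts[1] < counts[2]

    def test_deterministic_under_seed(self, default_config):
        profile = SubjectProfile("S", "HS", base_area_mm2=100.0, seq_effect=1.0)
        a, _ = render_sheet(profile, "name", default_config, seed=2)
        b, _ = render_sheet(profile, "name", default_config, seed=2)
        assert np.array_equal(a, b)

    def test_infeasible_area_names_the_row(self, default_config):
        profile = SubjectProfile("S", "HS", base_area_mm2=9000.0, seq_effect=1.0)
        with pytest.raises(GenerationError, match="row 1"):
            render_sheet(profile, "sentence", default_config, seed=0)


class TestScanArtifacts:
    def test_zero_params_identity(self, hs_sheet):
        page, _ = hs_sheet
        out, angle = add_scan_artifacts(
            page, ArtifactParams(rotation_deg=0, illumination=0, noise_sd=0), seed=1
        )
        assert angle == 0.0
        assert np.array_equal(out, page)

    def test_deterministic_under_seed(self, hs_sheet):
        page, _ = hs_sheet
        a, ang_a = add_scan_artifacts(page, ArtifactParams(), seed=13)
        b, ang_b = add_scan_artifacts(page, ArtifactParams(), seed=13)
        assert ang_a == ang_b
        assert np.array_equal(a, b)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(rotation_deg=4.0), dict(illumination=0.3), dict(noise_sd=0.2)],
    )
    def test_out_of_bounds_params_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ArtifactParams(**kwargs)

    def test_artifact_round_trip_within_5pct(self, default_config):
        """Default scan artifacts leave measured areas within 5% of truth."""
        from penstroke.pipeline import measure_page

        worst = 0.0
        for seed, (group, base, seq) in enumerate(
            [("HS", 126.72, 1.05), ("PD", 89.78, 0.92)]
        ):
            profile = SubjectProfile(
                f"S{seed}", group,
                stage="early" if group == "PD" else "none",
                state="OFF" if group == "PD" else "none",
                base_area_mm2=base, seq_effect=seq,
            )
            page, gt = render_sheet(profile, "sentence", default_config, seed=seed)
            noisy, _ = add_scan_artifacts(page, ArtifactParams(), seed=seed + 40)
            rows = measure_page(noisy, gt.calibration, 10, apply_deskew=True)
            areas = np.array([r.ink_area_mm2 for r in rows])
            target = np.array(gt.target_areas_mm2)
            worst = max(worst, float(np.abs(areas / target - 1).max()))
        assert worst <= 0.05


class TestWriteDataset:
    def test_one_page_per_subject_task(self, tmp_path):
        config = GeneratorConfig(dpi=150)
        profiles = sample_subject_profiles(config, {"HS": 1, "PD_OFF": 1}, seed=0)
        manifest = write_dataset(profiles, config, tmp_path)
        assert len(manifest) == 4  # 2 subjects x 2 tasks
        assert len(list(tmp_path.glob("*.png"))) == 4
        for rec in manifest.itertuples():
            assert (tmp_path / rec.path).exists()
            gt = SheetGroundTruth.from_json((tmp_path / rec.gt_path).read_text())
            assert gt.subject_id == rec.subject_id

    def test_empty_profiles_empty_manifest(self, tmp_path):
        manifest = write_dataset([], GeneratorConfig(dpi=150), tmp_path)
        assert manifest.empty
        assert not list(tmp_path.glob("*.png"))

    def test_refuses_overwrite_without_flag(self, tmp_path):
        config = GeneratorConfig(dpi=150, tasks_per_subject=1)
        profiles = sample_subject_profiles(config, {"HS": 1}, seed=0)
        write_dataset(profiles, config, tmp_path)
        with pytest.raises(ConfigurationError, match="overwrite"):
            write_dataset(profiles, config, tmp_path)
        write_dataset(profiles, config, tmp_path, overwrite=True)


class TestConfigValidation:
    def test_rows_per_sheet_minimum(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(rows_per_sheet=1)

    def test_calibration_follows_dpi(self):
        config = GeneratorConfig(dpi=254.0)
        assert config.calibration == pytest.approx(0.1)
        h, w = config.page_shape
        assert (h, w) == (2970, 2100)

    def test_negative_area_mean_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(group_area_params={"HS": (-5.0, 1.0)})

    def test_profile_invariants(self):
        with pytest.raises(ConfigurationError):
            SubjectProfile("x", "PD", stage="none", state="OFF")
        with pytest.raises(ConfigurationError):
            SubjectProfile("x", "HS", stage="early")
        with pytest.raises(ConfigurationError):
            SubjectProfile("x", "HS", base_area_mm2=-1.0)
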