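"""Synthetic humidistat study: cohort, walk dynamics, water records, file bundle."""

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from humidistat import arena as arena_mod
from humidistat import pipeline, tracks
from humidistat.arena import ArenaSpec
from humidistat.synthstudy import (
    FieldTruth,
    StudyConfig,
    generate_study,
    make_cohort,
    simulate_study_tables,
    simulate_trajectory,
    simulate_water_records,
    true_field,
    _folded_walk,
)


class TestMakeCohort:
    def test_default_cohort_size_and_sex_balance(self):
        cohort = make_cohort(StudyConfig(), seed=1)
        assert len(cohort) == 44
        assert (cohort["sex"] == "F").sum() == 22
        assert (cohort["sex"] == "M").sum() == 22

    def test_deterministic_for_fixed_seed(self):
        a = make_cohort(StudyConfig(), seed=5)
        b = make_cohort(StudyConfig(), seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = make_cohort(StudyConfig(), seed=6)
        assert not np.allclose(a["mass_g"], c["mass_g"])

    def test_mass_scale_matches_cohort(self):
        cohort = make_cohort(StudyConfig(), seed=2)
        assert cohort["mass_g"].mean() == pytest.approx(12.0, abs=1.5)
        assert (cohort["mass_g"] > 0).all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            StudyConfig(n_animals=0)


class TestFoldedWalk:
    def test_unbiased_walk_occupancy_uniform(self):
        # null model: no VPD-seeking drift -> uniform occupancy on [0, 180].
        # The chain is autocorrelated, so thin to near-independence before the
        # goodness-of-fit test.
        cfg = StudyConfig(bias_strength_deg_per_kPa=0.0)
        fld = true_field(cfg, 17.0)
        rng = np.random.default_rng(99)
        walk = _folded_walk(100_001, 0.56, fld, cfg, rng)
        thinned = walk[2000::500]
        counts, _ = np.histogram(thinned, bins=6, range=(0.0, 180.0))
        p = scipy.stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_degenerate_config_rejected(self):
        cfg = StudyConfig(step_angle_sd_deg=0.0, bias_strength_deg_per_kPa=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            _folded_walk(100, 0.56, true_field(cfg, 17.0), cfg, np.random.default_rng(0))

    def test_stays_on_folded_interval(self):
        cfg = StudyConfig()
        walk = _folded_walk(
            5000, 0.56, true_field(cfg, 22.0), cfg, np.random.default_rng(3)
        )
        assert walk.min() >= 0.0 and walk.max() <= 180.0
        assert walk[0] == 90.0  # released at the intermediate compartment

    def test_bias_strength_tightens_vpd_selection(self):
        # truth-tracking: stronger humidistat drift -> smaller cohort SD of
        # the trial-median selected VPD (3-point monotonicity, seeded)
        sds = []
        for bias in (0.2, 0.8, 3.0):
            cfg = StudyConfig(
                n_animals=16, n_frames=200, frame_interval_s=216.0,
                bias_strength_deg_per_kPa=bias,
            )
            tabs = simulate_study_tables(cfg, seed=44)
            sds.append(tabs.analysis_table["median_vpd"].std())
        assert sds[0] > sds[1] > sds[2]


class TestSimulateTrajectory:
    def test_same_seed_bit_identical(self):
        cfg = StudyConfig(n_frames=300)
        animal = make_cohort(cfg, 1).iloc[0]
        fld = true_field(cfg, 17.0)
        t1 = simulate_trajectory(animal, fld, 17.0, cfg, seed=7)
        t2 = simulate_trajectory(animal, fld, 17.0, cfg, seed=7)
        pd.testing.assert_frame_equal(t1.frames, t2.frames)

    def test_never_leaves_annulus_or_lane(self):
        cfg = StudyConfig(n_frames=2000)
        arena = ArenaSpec()
        animal = make_cohort(cfg, 1).iloc[0]
        for lane, lo, hi in [("inner", 30.0, 37.5), ("outer", 37.5, 45.0)]:
            traj = simulate_trajectory(
                animal, true_field(cfg, 17.0), 17.0, cfg, seed=8, lane=lane, arena=arena
            )
            r_px, _ = arena_mod.cartesian_to_polar(
                traj.frames["x_px"].to_numpy(), traj.frames["y_px"].to_numpy(),
                arena.centroid_px,
            )
            r_cm = r_px / arena.px_per_cm
            assert r_cm.min() >= lo and r_cm.max() <= hi

    def test_field_temperature_mismatch_rejected(self):
        cfg = StudyConfig()
        animal = make_cohort(cfg, 1).iloc[0]
        with pytest.raises(ValueError, match="temperature"):
            simulate_trajectory(animal, true_field(cfg, 17.0), 22.0, cfg, seed=1)


class TestSimulateWaterRecords:
    @staticmethod
    def _noiseless_config(**kw):
        base = dict(
            ewl_coeff=0.004, ewl_mass_exponent=1.0, ewl_noise_sd=0.0,
            rer_noise_sd=0.0, mass_trial_jitter_sd=0.0,
        )
        base.update(kw)
        return StudyConfig(**base)

    @staticmethod
    def _summary(vpd, temp):
        return tracks.AnimalSummary(
            animal_id="A01", sex="F", test_temperature_C=temp,
            median_selected_vpd_kPa=vpd,
            median_selected_rh_pct=70.0, total_distance_m=40.0,
            n_experimental_frames=1080,
        )

    def test_noiseless_closed_form(self):
        cfg = self._noiseless_config()
        animal = pd.Series({"animal_id": "A01", "mass_g": 12.0})
        rec = simulate_water_records(animal, self._summary(0.56, 17.0), cfg, seed=0)
        assert rec.ewl_ml_per_h == pytest.approx(0.004 * 12.0 * 0.56)  # 0.0269
        assert rec.mass_post_g == pytest.approx(12.0 - 0.0269 * 12.0, abs=1e-3)

    def test_rer_follows_q10_law(self):
        cfg = self._noiseless_config()
        animal = pd.Series({"animal_id": "A01", "mass_g": 12.0})
        r17 = simulate_water_records(animal, self._summary(0.56, 17.0), cfg, seed=0)
        r22 = simulate_water_records(animal, self._summary(0.56, 22.0), cfg, seed=0)
        assert r22.rer_ml_per_h / r17.rer_ml_per_h == pytest.approx(2.5**0.5)

    def test_equal_masses_equal_loss_without_noise(self):
        cfg = self._noiseless_config()
        s = self._summary(0.56, 17.0)
        recs = [
            simulate_water_records(
                pd.Series({"animal_id": f"A{i}", "mass_g": 10.0}), s, cfg, seed=i
            )
            for i in range(3)
        ]
        losses = {round(r.mass_loss_pct, 12) for r in recs}
        assert len(losses) == 1

    def test_rehydration_capped_at_pre_mass(self):
        cfg = self._noiseless_config(rer_base_ml_per_h=50.0)
        animal = pd.Series({"animal_id": "A01", "mass_g": 12.0})
        rec = simulate_water_records(animal, self._summary(0.56, 17.0), cfg, seed=0)
        assert rec.mass_rehydrated_g == pytest.approx(rec.mass_pre_g)

    def test_exhausting_mass_rejected(self):
        cfg = self._noiseless_config(ewl_coeff=1.0)
        animal = pd.Series({"animal_id": "A01", "mass_g": 5.0})
        with pytest.raises(ValueError, match="mass"):
            simulate_water_records(animal, self._summary(1.0, 17.0), cfg, seed=0)


class TestGenerateStudy:
    SMALL = dict(n_animals=4, n_frames=200, frame_interval_s=216.0, logger_duration_h=2.0)

    def test_bundle_round_trips_through_readers(self, tmp_path):
        cfg = StudyConfig(**self.SMALL)
        paths = generate_study(cfg, seed=21, out_dir=tmp_path)
        fields = {}
        for t, p in paths["loggers"].items():
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                recs = arena_mod.read_logger_csv(p)
                fields[t] = arena_mod.fit_humidity_field(recs, t)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            result = pipeline.process_study(paths["manifest"], fields, paths["masses"])
        table = result["analysis_table"]
        assert len(table) == 2 * cfg.n_animals
        assert table["median_vpd"].between(0.0, 1.5).all()
        truth = json.loads(paths["truth"].read_text())
        assert truth["target_vpd_kPa"] == 0.56

    def test_file_pipeline_matches_in_memory_study(self, tmp_path):
        cfg = StudyConfig(**self.SMALL)
        tabs = simulate_study_tables(cfg, seed=22)
        paths = generate_study(cfg, seed=22, out_dir=tmp_path)
        fields = {
            t: arena_mod.fit_humidity_field(arena_mod.read_logger_csv(p), t)
            for t, p in paths["loggers"].items()
        }
        result = pipeline.process_study(paths["manifest"], fields, paths["masses"])
        a = tabs.analysis_table.sort_values(["animal_id", "temperature"]).reset_index(drop=True)
        b = result["analysis_table"].sort_values(["animal_id", "temperature"]).reset_index(drop=True)
        # tracking pixels are written at 2 dp (0.1 cm), masses at 4 dp
        assert b["median_rh"].to_numpy() == pytest.approx(a["median_rh"].to_numpy(), abs=0.05)
        assert b["median_vpd"].to_numpy() == pytest.approx(a["median_vpd"].to_numpy(), abs=0.005)
        assert b["total_distance_m"].to_numpy() == pytest.approx(
            a["total_distance_m"].to_numpy(), abs=0.05
        )
        assert b["log_ewl"].to_numpy() == pytest.approx(a["log_ewl"].to_numpy(), abs=0.01)

    def test_fixed_master_seed_byte_identical(self, tmp_path):
        cfg = StudyConfig(**self.SMALL)
        h = []
        for sub in ("a", "b"):
            d = tmp_path / sub
            generate_study(cfg, seed=33, out_dir=d)
            digest = hashlib.sha256()
            for p in sorted(d.rglob("*")):
                if p.is_file():
                    digest.update(p.name.encode())
                    digest.update(p.read_bytes())
            h.append(digest.hexdigest())
        assert h[0] == h[1]


class TestStudyTables:
    def test_default_design_has_88_trials(self, fast_study):
        assert len(fast_study.analysis_table) == 88
        assert fast_study.analysis_table["animal_id"].nunique() == 44

    def test_summaries_respect_field_monotonicity(self, fast_study):
        for t, fld in fast_study.fitted_fields.items():
            assert arena_mod.field_vpd_at(fld, 0.0) >= arena_mod.field_vpd_at(fld, 180.0)

    def test_truth_records_generator_parameters(self, fast_study):
        truth = fast_study.truth
        assert truth["rer_q10"] == 2.5
        assert truth["implied_rh_temperature_offset_pct"] == pytest.approx(7.73, abs=0.05)
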