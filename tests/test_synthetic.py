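"""The synthetic cohort generator: structure, determinism, ground-truth links."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from svdmarkers.calibration import null_calibration_study
from svdmarkers.errors import ConfigError, GenerationError
from svdmarkers.models import standardized_linear_model
from svdmarkers.segmentation import TissueLabel, hard_segment, make_masks
from svdmarkers.synthetic import (
    GeneratorConfig,
    SiteSpec,
    TissueDistribution,
    generate_analysis_cohort,
    generate_cognition,
    generate_cohort,
    generate_subject_imaging,
    read_cohort,
    synthetic_normative_table,
    write_cohort,
)


class TestConfigValidation:
    def test_bad_probability_names_field(self):
        cfg = dataclasses.replace(GeneratorConfig(), p_unable=1.5)
        with pytest.raises(ConfigError, match="p_unable"):
            cfg.validate()

    def test_negative_site_n(self):
        cfg = dataclasses.replace(GeneratorConfig(), sites=(SiteSpec(1, -2),))
        with pytest.raises(ConfigError, match="n_subjects"):
            cfg.validate()

    def test_wmh_must_look_degraded(self):
        tm = dict(GeneratorConfig().tissue_means)
        tm["wmh"] = TissueDistribution(0.5, 0.1, 0.9e-3, 1e-4)  # FA above NAWM
        cfg = dataclasses.replace(GeneratorConfig(), tissue_means=tm)
        with pytest.raises(ConfigError, match="fa_mean"):
            cfg.validate()

    def test_md_mean_range(self):
        tm = dict(GeneratorConfig().tissue_means)
        tm["csf"] = TissueDistribution(0.1, 0.05, 5e-3, 1e-4)
        cfg = dataclasses.replace(GeneratorConfig(), tissue_means=tm)
        with pytest.raises(ConfigError, match="md_mean"):
            cfg.validate()


class TestCohortStructure:
    def test_per_site_counts_match_enrolment(self, small_bundle, small_config):
        counts = small_bundle.cohort["site"].value_counts().to_dict()
        assert counts == {s.site_id: s.n_subjects for s in small_config.sites}
        assert len(small_bundle.subjects) == small_config.total_n

    def test_seeded_determinism(self, small_config, small_bundle):
        again = generate_cohort(small_config)
        pd.testing.assert_frame_equal(small_bundle.cohort, again.cohort)
        pd.testing.assert_frame_equal(small_bundle.ground_truth, again.ground_truth)
        for a, b in zip(small_bundle.subjects, again.subjects):
            assert np.array_equal(a.fa.values, b.fa.values)
            assert np.array_equal(a.wmh_mask.values, b.wmh_mask.values)

    def test_tpm_partition_of_unity(self, small_bundle):
        for s in small_bundle.subjects:
            total = s.tpm_sum
            in_brain = total > 0
            assert np.all(np.abs(total[in_brain] - 1.0) < 1e-6)

    def test_wmh_only_in_dominant_wm(self, small_bundle):
        for s in small_bundle.subjects:
            lesioned = s.wmh_mask.values == 1
            if lesioned.any():
                dominant_wm = (s.tpm_wm.values > s.tpm_gm.values) & (
                    s.tpm_wm.values > s.tpm_csf.values
                )
                assert np.all(dominant_wm[lesioned])

    def test_wmh_fraction_negatively_tracks_integrity(self):
        cfg = dataclasses.replace(GeneratorConfig(seed=7), sites=(SiteSpec(1, 40),))
        bundle = generate_cohort(cfg)
        gt = bundle.ground_truth
        assert gt["latent_integrity"].corr(gt["wmh_voxels"]) < -0.2

    def test_latent_integrity_recorded(self, small_bundle):
        assert np.all(np.isfinite(small_bundle.ground_truth["latent_integrity"]))


class TestSubjectImaging:
    CFG = GeneratorConfig(seed=0)
    SITE = SiteSpec(1, 1)

    def test_grid_too_small_errors(self):
        cfg = dataclasses.replace(self.CFG, grid_shape=(6, 6, 6))
        with pytest.raises(GenerationError, match="grid"):
            generate_subject_imaging(0.0, self.SITE, cfg, np.random.default_rng(0))

    def test_lesion_free_subject_has_equal_masks(self):
        cfg = dataclasses.replace(self.CFG, wmh_load_mean_pct=0.0, wmh_load_sd_pct=0.0)
        subj = generate_subject_imaging(0.0, self.SITE, cfg, np.random.default_rng(1))
        assert subj.wmh_mask.values.sum() == 0
        masks = make_masks(
            hard_segment(subj.tpm_gm, subj.tpm_wm, subj.tpm_csf, subj.wmh_mask)
        )
        assert np.array_equal(masks.nawm_mask, masks.allwm_mask)

    def test_md_site_offset_shifts_wm_mean(self):
        """A +1e-4 mm^2/s scanner offset moves the mean WM MD by +1e-4
        (difference of means over 50 matched replicate subjects)."""
        offset = 1.0e-4
        diffs = []
        for i in range(50):
            base = generate_subject_imaging(
                0.0, SiteSpec(1, 1, 0.0, 0.0), self.CFG, np.random.default_rng(1000 + i)
            )
            shifted = generate_subject_imaging(
                0.0, SiteSpec(2, 1, 0.0, offset), self.CFG, np.random.default_rng(1000 + i)
            )
            for subj, acc in ((base, 0), (shifted, 1)):
                labels = hard_segment(
                    subj.tpm_gm, subj.tpm_wm, subj.tpm_csf, subj.wmh_mask
                )
                wm = labels.labels == int(TissueLabel.WM)
                if acc == 0:
                    m0 = subj.md.values[wm].mean()
                else:
                    diffs.append(subj.md.values[wm].mean() - m0)
        assert np.mean(diffs) == pytest.approx(offset, abs=1.5e-5)

    def test_low_integrity_means_larger_expected_lesions(self):
        loads = {}
        for integrity in (-2.0, 2.0):
            vox = []
            for i in range(30):
                subj = generate_subject_imaging(
                    integrity, self.SITE, self.CFG, np.random.default_rng(2000 + i)
                )
                vox.append(subj.wmh_mask.values.sum())
            loads[integrity] = np.mean(vox)
        assert loads[-2.0] > loads[2.0]

    def test_spurious_fa_exercises_cleaning_rule(self):
        subj = generate_subject_imaging(
            0.0, self.SITE, dataclasses.replace(self.CFG, spurious_fa_frac=0.01),
            np.random.default_rng(3),
        )
        assert (subj.fa.values > 1.0).sum() > 0
        assert subj.fa.values.max() <= 1.2


class TestCognition:
    CFG = GeneratorConfig(seed=0)
    DEMO = {"age": 68.0, "sex": 1, "premorbid_iq": 116.0}

    def test_no_missingness_when_probabilities_zero(self):
        cfg = dataclasses.replace(self.CFG, p_unable=0.0, p_other=0.0)
        bundle = generate_cohort(
            dataclasses.replace(cfg, sites=(SiteSpec(1, 20),))
        )
        from svdmarkers.cognition import TASKS

        for t in TASKS:
            assert (bundle.cohort[f"{t}_missing"] == "").all()

    def test_score_ranges(self):
        rng = np.random.default_rng(4)
        rows = [
            generate_cognition(rng.standard_normal(), self.DEMO, self.CFG, rng)
            for _ in range(200)
        ]
        df = pd.DataFrame(rows)
        assert df["moca"].between(0, 30).all()
        assert (df["moca"] == df["moca"].round()).all()  # integer scale
        assert df["ssqol"].between(49, 245).all()
        assert df["euroqol"].between(0, 100).all()

    def test_missing_demographics_errors(self):
        with pytest.raises(ConfigError, match="age"):
            generate_cognition(0.0, {"sex": 1, "premorbid_iq": 100}, self.CFG,
                               np.random.default_rng(0))

    def test_timed_tasks_emitted_higher_is_worse(self):
        # a strongly impaired subject should have *longer* TMT times
        rng = np.random.default_rng(5)
        norms = synthetic_normative_table()
        good = [generate_cognition(2.5, self.DEMO, self.CFG, rng) for _ in range(40)]
        bad = [generate_cognition(-2.5, self.DEMO, self.CFG, rng) for _ in range(40)]
        tmt_good = np.nanmean([g["tmt_b"] for g in good])
        tmt_bad = np.nanmean([b["tmt_b"] for b in bad])
        assert tmt_bad > tmt_good


class TestRoundTrip:
    def test_write_read_bit_exact(self, small_bundle, tmp_path):
        out = write_cohort(small_bundle, tmp_path / "cohort")
        subjects, cohort = read_cohort(out)
        assert len(cohort) == small_bundle.config.total_n
        for a, b in zip(small_bundle.subjects, subjects):
            assert np.array_equal(a.fa.values, b.fa.values)
            assert np.array_equal(a.md.values, b.md.values)
            assert np.array_equal(a.wmh_mask.values, b.wmh_mask.values)
        import json

        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == small_bundle.config.seed


class TestCalibrationCohort:
    def test_noiseless_linear_recovery(self):
        """With zero residual noise and covariate effects, the raw slope of
        the outcome on latent integrity equals the configured effect exactly
        and the standardized coefficient is 1."""
        df = generate_analysis_cohort(
            n=60, seed=9, true_beta=0.30,
            covariate_effects={"age": 0, "sex": 0, "premorbid_iq": 0},
            residual_sd=0.0,
        )
        res = standardized_linear_model(
            df, "global_cognition", ["integrity"], covariates=(), site_col=None
        )
        est = res.term("integrity")
        assert est.beta_raw == pytest.approx(0.30, abs=1e-6)
        assert est.beta == pytest.approx(1.0, abs=1e-6)

    def test_fa_readout_is_affine_in_integrity(self):
        df = generate_analysis_cohort(n=50, seed=10)
        r = np.corrcoef(df["integrity"], df["fa_median_wm"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_null_pvalues_are_uniform(self):
        """With a zero true effect, Simple-model p-values for the DTI
        predictor pass a KS uniformity check over 500 replicates."""
        res = null_calibration_study(n=80, n_replicates=500, seed=13)
        assert res["ks_p"] > 0.01
        assert res["significant_rate"] < 0.09
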