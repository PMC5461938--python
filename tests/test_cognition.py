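"""Z-transforms, missing-data rules, domain composites and the exclusion ledger."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svdmarkers.cognition import (
    DOMAIN_TASKS,
    DOMAINS,
    OTHER,
    TASKS,
    UNABLE,
    domain_scores,
    exclusion_ledger,
    impairment_tests,
    impute_unable,
    z_transform,
)
from svdmarkers.datasets import example_enrolment_table, example_unable_pattern
from svdmarkers.errors import DegenerateDataError, NormLookupError
from svdmarkers.synthetic import synthetic_normative_table

NORMS = synthetic_normative_table()


class TestZTransform:
    def test_raw_equal_to_norm_mean_is_zero(self):
        mean, sd, _ = NORMS.lookup("dsc", 65)
        assert z_transform(mean, "dsc", 65, NORMS) == 0.0

    def test_timed_task_orientation_flip(self):
        # one SD slower than the norm on TMT-B means z = -1
        mean, sd, orientation = NORMS.lookup("tmt_b", 65)
        assert orientation == "higher_worse"
        assert z_transform(mean + sd, "tmt_b", 65, NORMS) == pytest.approx(-1.0)

    def test_two_sd_above_on_accuracy_task(self):
        mean, sd, _ = NORMS.lookup("fas", 50)
        assert z_transform(mean + 2 * sd, "fas", 50, NORMS) == pytest.approx(2.0)

    def test_age_outside_support_names_task(self):
        with pytest.raises(NormLookupError, match="dsc"):
            z_transform(50, "dsc", 120, NORMS)


def _z_frame(values_by_task, n=None):
    n = n or max(len(v) for v in values_by_task.values())
    data = {t: values_by_task.get(t, [0.0] * n) for t in TASKS}
    return pd.DataFrame(data, index=[f"S{i}" for i in range(n)])


def _empty_reasons(index):
    return pd.DataFrame("", index=index, columns=list(TASKS))


class TestImputeUnable:
    def test_minimum_of_listed_values(self):
        z = _z_frame({"dsc": [-1.2, 0.3, -2.5, np.nan]})
        reasons = _empty_reasons(z.index)
        reasons.loc["S3", "dsc"] = UNABLE
        out, log = impute_unable(z, reasons)
        assert out.loc["S3", "dsc"] == -2.5
        assert log.n_tasks == 1 and log.n_participants == 1

    def test_no_unable_entries_is_identity(self):
        z = _z_frame({"dsc": [0.1, -0.4]})
        out, log = impute_unable(z, _empty_reasons(z.index))
        pd.testing.assert_frame_equal(out, z)
        assert log.n_tasks == 0 and log.entries == []

    def test_unable_with_no_observed_values_errors(self):
        z = _z_frame({"tmt_a": [np.nan, np.nan]})
        reasons = _empty_reasons(z.index)
        reasons["tmt_a"] = UNABLE
        with pytest.raises(DegenerateDataError, match="tmt_a"):
            impute_unable(z, reasons)

    def test_imputed_value_equals_cohort_minimum_property(self, rng):
        z = pd.DataFrame(
            rng.normal(size=(30, len(TASKS))), columns=list(TASKS),
            index=[f"S{i}" for i in range(30)],
        )
        reasons = _empty_reasons(z.index)
        for t in TASKS[:4]:
            victim = rng.choice(z.index)
            z.loc[victim, t] = np.nan
            reasons.loc[victim, t] = UNABLE
        out, log = impute_unable(z, reasons)
        for subj, task in log.entries:
            assert out.loc[subj, task] == z[task].min()

    def test_subject_min_variant(self):
        z = _z_frame({"dsc": [np.nan, 0.0], "tmt_a": [-0.7, 0.1], "fas": [-0.2, 0.4]})
        reasons = _empty_reasons(z.index)
        reasons.loc["S0", "dsc"] = UNABLE
        out, _ = impute_unable(z, reasons, strategy="subject_min")
        assert out.loc["S0", "dsc"] == -0.7  # the subject's own lowest z

    def test_example_pattern_reports_thirteen_of_109(self):
        z, reasons = example_unable_pattern()
        _, log = impute_unable(z, reasons)
        assert log.n_tasks == 15
        assert log.n_participants == 13
        assert round(log.pct_participants, 1) == 11.9


class TestDomainScores:
    def test_all_zero_tasks(self):
        z = _z_frame({}, n=3)
        d = domain_scores(z)
        assert (d[list(DOMAINS) + ["global_cognition"]] == 0).all().all()

    def test_other_missing_task_dropped_from_domain(self):
        z = _z_frame({"fas": [0.8], "animals": [np.nan]}, n=1)
        d = domain_scores(z)
        assert d.loc["S0", "verbal_fluency"] == pytest.approx(0.8)

    def test_processing_speed_mean(self):
        z = _z_frame({"dsc": [1.0], "tmt_a": [0.0]}, n=1)
        assert domain_scores(z).loc["S0", "processing_speed"] == pytest.approx(0.5)

    def test_global_missing_when_domain_missing(self):
        z = _z_frame({"tmt_b": [np.nan]}, n=1)
        d = domain_scores(z)
        assert np.isnan(d.loc["S0", "mental_flexibility"])
        assert np.isnan(d.loc["S0", "global_cognition"])

    def test_permutation_invariance(self, rng):
        z = pd.DataFrame(
            rng.normal(size=(10, len(TASKS))), columns=list(TASKS),
            index=[f"S{i}" for i in range(10)],
        )
        base = domain_scores(z)
        shuffled = domain_scores(z[list(reversed(TASKS))])
        pd.testing.assert_frame_equal(base, shuffled)

    def test_global_equals_mean_of_domains(self, rng):
        z = pd.DataFrame(
            rng.normal(size=(10, len(TASKS))), columns=list(TASKS),
            index=[f"S{i}" for i in range(10)],
        )
        d = domain_scores(z)
        expected = d[list(DOMAINS)].mean(axis=1)
        pd.testing.assert_series_equal(d["global_cognition"], expected, check_names=False)


class TestImpairmentTests:
    def _frame(self, values):
        return pd.DataFrame({d: values for d in list(DOMAINS) + ["global_cognition"]})

    def test_impaired_group_significant(self):
        res = impairment_tests(self._frame([-1.1, -0.9, -1.0, -1.0]))
        # closed-form oracle: t = mean / (sd/sqrt(n))
        vals = np.array([-1.1, -0.9, -1.0, -1.0])
        t_exp = vals.mean() / (vals.std(ddof=1) / 2)
        p_exp = 2 * stats.t.sf(abs(t_exp), df=3)
        for r in res:
            assert r.t == pytest.approx(t_exp)
            assert r.p == pytest.approx(p_exp)
            assert r.p < 0.05

    def test_zero_variance_errors(self):
        with pytest.raises(DegenerateDataError):
            impairment_tests(self._frame([0.0, 0.0, 0.0, 0.0]))

    def test_too_small_errors(self):
        with pytest.raises(DegenerateDataError):
            impairment_tests(self._frame([-1.0, 0.5]))


class TestExclusionLedger:
    OUTCOMES = [
        "global_cognition", "processing_speed", "mental_flexibility",
        "verbal_fluency", "verbal_memory", "moca", "ssqol", "euroqol",
    ]

    def test_study_configuration_arithmetic(self):
        df = example_enrolment_table()
        ledger = exclusion_ledger(df, self.OUTCOMES)
        assert ledger.cohort_n == 109
        assert ledger.n_complete_imaging == 102
        assert ledger.n_per_outcome["verbal_fluency"] == 99
        for o in self.OUTCOMES:
            if o != "verbal_fluency":
                assert ledger.n_per_outcome[o] == 100

    def test_no_exclusions(self):
        df = example_enrolment_table()
        df = df[df["site"] != 6].copy()
        df["mri_fail"] = False
        df["premorbid_iq"] = 1.0
        for o in self.OUTCOMES:
            df[o] = 0.0
        ledger = exclusion_ledger(df, self.OUTCOMES)
        assert ledger.n_complete_imaging == len(df)
        assert all(n == len(df) for n in ledger.n_per_outcome.values())

    def test_ledger_monotone_under_extra_flags(self, rng):
        df = example_enrolment_table()
        before = exclusion_ledger(df, self.OUTCOMES)
        df2 = df.copy()
        extra = rng.choice(df2.index[~df2["mri_fail"]], size=3, replace=False)
        df2.loc[extra, "mri_fail"] = True
        after = exclusion_ledger(df2, self.OUTCOMES)
        assert after.n_complete_imaging <= before.n_complete_imaging
        for o in self.OUTCOMES:
            assert after.n_per_outcome[o] <= before.n_per_outcome[o]
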