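"""Standardized-beta regressions, the selection rule and Complex models."""

import numpy as np
import pandas as pd
import pytest

from svdmarkers.datasets import example_simple_screen
from svdmarkers.errors import CollinearityError, SampleSizeError
from svdmarkers.models import (
    complex_models,
    select_variables,
    simple_models,
    standardized_linear_model,
)
from svdmarkers.synthetic import generate_analysis_cohort

from _regression_oracle import ols_oracle


def test_identity_fit():
    df = pd.DataFrame({"x": np.arange(20.0), "y": np.arange(20.0)})
    res = standardized_linear_model(df, "y", ["x"], covariates=(), site_col=None)
    est = res.term("x")
    assert est.beta == pytest.approx(1.0, abs=1e-10)
    assert res.adjusted_r2 == pytest.approx(1.0, abs=1e-10)


def test_orthogonal_predictors_unit_vif(rng):
    n = 64
    q, _ = np.linalg.qr(rng.normal(size=(n, 3)))
    q -= q.mean(axis=0)  # exactly orthogonal to the intercept too
    q, _ = np.linalg.qr(q)
    df = pd.DataFrame(q, columns=["a", "b", "c"])
    df["y"] = rng.normal(size=n)
    res = standardized_linear_model(df, "y", ["a", "b", "c"], covariates=(), site_col=None)
    for t in ("a", "b", "c"):
        assert res.term(t).vif == pytest.approx(1.0, abs=1e-8)


def test_matches_normal_equations_oracle(rng):
    """beta, p, CI, adjusted R^2 and VIF agree with an independent
    matrix-algebra oracle to 1e-8 on random multi-site instances."""
    for _ in range(100):
        n = 200
        df = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "age": rng.normal(68, 9, n),
                "sex": rng.integers(0, 2, n).astype(float),
                "premorbid_iq": rng.normal(116, 8, n),
                "site": rng.integers(1, 4, n),
            }
        )
        df["y"] = (
            0.4 * df.x1 - 0.2 * df.x2 + 0.01 * df.age + rng.normal(size=n)
        )
        res = standardized_linear_model(df, "y", ["x1", "x2"])
        oracle = ols_oracle(
            df, "y", ["x1", "x2", "age", "sex", "premorbid_iq"], site_col="site"
        )
        for term in ("x1", "x2", "age", "premorbid_iq"):
            est = res.term(term)
            assert est.beta == pytest.approx(oracle[term]["std_beta"], abs=1e-8)
            assert est.p_value == pytest.approx(oracle[term]["p"], abs=1e-8)
            assert est.ci_lo == pytest.approx(oracle[term]["std_ci"][0], abs=1e-8)
            assert est.ci_hi == pytest.approx(oracle[term]["std_ci"][1], abs=1e-8)
            assert est.vif == pytest.approx(oracle[term]["vif"], abs=1e-8)
        sex = res.term("sex")  # indicator: reported unstandardized
        assert sex.beta == pytest.approx(oracle["sex"]["b"], abs=1e-8)
        assert res.adjusted_r2 == pytest.approx(oracle["_model"]["adj_r2"], abs=1e-8)
        assert res.n == oracle["_model"]["n"]


def test_simple_beta_equals_pearson_r(rng):
    n = 151
    x = rng.normal(size=n)
    y = 0.5 * x + rng.normal(size=n)
    df = pd.DataFrame({"x": x, "y": y})
    res = standardized_linear_model(df, "y", ["x"], covariates=(), site_col=None)
    r = np.corrcoef(x, y)[0, 1]
    assert res.term("x").beta == pytest.approx(r, abs=1e-10)


def test_rank_deficiency_errors(rng):
    n = 40
    x = rng.normal(size=n)
    df = pd.DataFrame({"x1": x, "x2": 2 * x, "y": rng.normal(size=n)})
    with pytest.raises(CollinearityError):
        standardized_linear_model(df, "y", ["x1", "x2"], covariates=(), site_col=None)


def test_small_n_errors(rng):
    df = pd.DataFrame({"x": rng.normal(size=3), "y": rng.normal(size=3)})
    with pytest.raises(SampleSizeError):
        standardized_linear_model(df, "y", ["x"], covariates=(), site_col=None)


def test_single_subject_site_errors():
    df = generate_analysis_cohort(n=41, seed=5, n_sites=2)
    df.loc[df.index[-1], "site"] = 9  # a stratum of one
    with pytest.raises(SampleSizeError, match="site"):
        standardized_linear_model(df, "global_cognition", ["fa_median_wm"])


def test_simple_models_count_and_direction():
    df = generate_analysis_cohort(n=400, seed=11, true_beta=0.35, n_sites=3)
    outcomes = ["global_cognition"]
    screen = simple_models(df, outcomes, tissue_class="wm")
    assert len(screen) == 7  # 3 NBV + WMH + lacunes + 2 DTI per outcome
    fa_row = screen[screen.variable == "fa_median_wm"].iloc[0]
    assert fa_row.standardized_beta > 0
    assert fa_row.p_value < 0.001
    wmh_row = screen[screen.variable == "wmh_lesion_load"].iloc[0]
    assert wmh_row.standardized_beta < 0  # higher lesion load, worse cognition


class TestSelection:
    def test_example_screen_global_cognition(self):
        screen = example_simple_screen()
        sel = select_variables(screen, "global_cognition", tissue_class="wm")
        assert sel.nbv_variable == "whole_nbv"  # minimum p among NBV variants
        # exact p tie between the two WM DTI metrics -> larger |beta| wins
        assert sel.dti_variable == "fa_median_wm"

    def test_example_screen_nawm(self):
        sel = select_variables(example_simple_screen(), "global_cognition", "nawm")
        assert sel.dti_variable == "fa_median_nawm"

    def test_absolute_beta_tie_break(self):
        screen = pd.DataFrame(
            {
                "category": ["nbv", "nbv", "dti", "dti"],
                "variable": ["a_nbv", "b_nbv", "fa_median_wm", "md_peak_height_wm"],
                "tissue_class": ["", "", "wm", "wm"],
                "outcome": ["y"] * 4,
                "standardized_beta": [0.2, -0.3, 0.1, 0.1],
                "p_value": [0.04, 0.04, 0.5, 0.6],
            }
        )
        sel = select_variables(screen, "y", "wm")
        assert sel.nbv_variable == "b_nbv"  # |-0.3| beats |0.2| at equal p

    def test_row_order_invariance(self, rng):
        screen = example_simple_screen()
        shuffled = screen.sample(frac=1.0, random_state=3)
        for outcome in screen.outcome.unique():
            a = select_variables(screen, outcome, "wm")
            b = select_variables(shuffled, outcome, "wm")
            assert (a.nbv_variable, a.dti_variable) == (b.nbv_variable, b.dti_variable)


def test_complex_equals_simple_for_orthogonal_design(rng):
    n = 128
    q, _ = np.linalg.qr(rng.normal(size=(n, 4)))
    q -= q.mean(axis=0)
    q, _ = np.linalg.qr(q)
    cols = ["whole_nbv", "wmh_lesion_load", "lacune_count", "fa_median_wm"]
    df = pd.DataFrame(q, columns=cols)
    df["y"] = rng.normal(size=n)
    betas_simple = {
        c: standardized_linear_model(df, "y", [c], covariates=(), site_col=None).term(c).beta
        for c in cols
    }
    complex_fit = standardized_linear_model(df, "y", cols, covariates=(), site_col=None)
    for c in cols:
        assert complex_fit.term(c).beta == pytest.approx(betas_simple[c], abs=1e-6)


def test_complex_models_shape_and_vif_gate():
    df = generate_analysis_cohort(n=300, seed=21, n_sites=3)
    outcomes = ["global_cognition"]
    screen = simple_models(df, outcomes, tissue_class="wm")
    sel = {o: select_variables(screen, o, "wm") for o in outcomes}
    results = complex_models(df, sel, outcomes)
    res = results["global_cognition"]
    assert {sel["global_cognition"].nbv_variable, "wmh_lesion_load",
            "lacune_count", sel["global_cognition"].dti_variable} <= set(res.terms)
    assert all(res.term(p).vif < 3 for p in res.terms)  # acceptable collinearity
    assert res.high_vif_terms == []
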