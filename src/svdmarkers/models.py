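"""Simple/Complex standardized-beta regressions with selection and VIF gating.

The association layer screens each MR variable separately against each
outcome ('Simple' models), selects per outcome the most significant NBV
variant and the most significant DTI histogram metric within a tissue class
(ties on p broken by the larger absolute standardized beta, then name
order), and refits all selected MR variables together ('Complex' models).
Every model controls for age, sex and premorbid IQ and is stratified by
study site via fixed-effect site indicators.  Coefficients are reported as
standardized betas, b * sd(x) / sd(y) over the analysis sample, with 95%
confidence intervals scaled identically; variance inflation factors flag
multicollinearity (VIF >= 3) and residuals are checked for normality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, SampleSizeError

DEFAULT_COVARIATES = ("age", "sex", "premorbid_iq")
#: Terms reported on their raw scale: binary/indicator variables.
DEFAULT_UNSTANDARDIZED = ("sex",)
#: VIF level treated as unacceptable multicollinearity.
VIF_LIMIT = 3.0

MR_CATEGORIES: Dict[str, Tuple[str, ...]] = {
    "nbv": ("whole_nbv", "gm_nbv", "wm_nbv"),
    "wmh": ("wmh_lesion_load",),
    "lacunes": ("lacune_count",),
}


def dti_variables(tissue_class: str) -> Tuple[str, str]:
    return (f"fa_median_{tissue_class}", f"md_peak_height_{tissue_class}")


@dataclass
class TermEstimate:
    term: str
    beta: float  # standardized unless standardized=False
    p_value: float
    ci_lo: float
    ci_hi: float
    vif: float
    standardized: bool = True
    # raw-scale (unstandardized) coefficient and CI, for reporting variants
    beta_raw: float = float("nan")
    ci_lo_raw: float = float("nan")
    ci_hi_raw: float = float("nan")


@dataclass
class RegressionResult:
    outcome: str
    terms: Dict[str, TermEstimate]
    adjusted_r2: float
    model_p: float
    n: int
    residual_normality_p: float
    high_vif_terms: List[str] = field(default_factory=list)

    def term(self, name: str) -> TermEstimate:
        return self.terms[name]


def _design_matrix(
    df: pd.DataFrame,
    predictors: Sequence[str],
    covariates: Sequence[str],
    site_col: str | None,
) -> Tuple[pd.DataFrame, List[str]]:
    cols = list(predictors) + [c for c in covariates if c not in predictors]
    X = df[cols].astype(float).copy()
    if site_col is not None:
        sites = sorted(df[site_col].unique())
        for s in sites[1:]:  # first site is the reference level
            X[f"site_{s}"] = (df[site_col] == s).astype(float)
    X = sm.add_constant(X, has_constant="add")
    return X, cols


def _vifs(X: pd.DataFrame) -> Dict[str, float]:
    """VIF of each non-constant column against all other columns."""
    out: Dict[str, float] = {}
    cols = [c for c in X.columns if c != "const"]
    arr = X.to_numpy()
    for j, c in enumerate(X.columns):
        if c == "const":
            continue
        others = np.delete(arr, j, axis=1)
        y = arr[:, j]
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        tss = np.sum((y - y.mean()) ** 2)
        if tss <= 0:
            raise CollinearityError(f"term {c!r} is constant in the analysis sample")
        r2 = 1.0 - np.sum(resid**2) / tss
        out[c] = float(1.0 / max(1.0 - r2, 1e-12))
    return out


def standardized_linear_model(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    site_col: str | None = "site",
    unstandardized_terms: Sequence[str] = DEFAULT_UNSTANDARDIZED,
    min_site_n: int = 2,
) -> RegressionResult:
    """OLS of ``outcome`` on predictors + covariates (+ site indicators).

    Complete-case analysis over the listed columns.  Standardized betas and
    CIs use the sample SDs of each term and of the outcome; site indicators
    and terms listed in ``unstandardized_terms`` are reported unscaled.
    """
    cols = [outcome] + list(predictors) + [c for c in covariates if c not in predictors]
    if site_col is not None:
        cols.append(site_col)
    df = data[cols].dropna()
    if site_col is not None:
        counts = df[site_col].value_counts()
        small = counts[counts < min_site_n]
        if not small.empty:
            raise SampleSizeError(
                f"sites {sorted(small.index)} have fewer than {min_site_n} subjects; "
                "exclude them before stratified fitting"
            )
    X, analysis_terms = _design_matrix(df, predictors, covariates, site_col)
    n, k = X.shape
    if n < k + 2:
        raise SampleSizeError(f"n={n} too small for {k} design columns (need >= {k + 2})")
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        raise CollinearityError(
            f"rank-deficient design for outcome {outcome!r}; terms: {list(X.columns)}"
        )
    y = df[outcome].astype(float)
    fit = sm.OLS(y.to_numpy(), X).fit()
    vifs = _vifs(X)
    sd_y = float(y.std(ddof=1))
    ci = fit.conf_int(alpha=0.05)
    terms: Dict[str, TermEstimate] = {}
    for t in analysis_terms:
        b_raw = float(fit.params[t])
        lo_raw, hi_raw = float(ci.loc[t, 0]), float(ci.loc[t, 1])
        b, lo, hi = b_raw, lo_raw, hi_raw
        standardized = t not in unstandardized_terms
        if standardized:
            scale = float(df[t].astype(float).std(ddof=1)) / sd_y
            b, lo, hi = b_raw * scale, lo_raw * scale, hi_raw * scale
        terms[t] = TermEstimate(
            term=t,
            beta=b,
            p_value=float(fit.pvalues[t]),
            ci_lo=lo,
            ci_hi=hi,
            vif=vifs[t],
            standardized=standardized,
            beta_raw=b_raw,
            ci_lo_raw=lo_raw,
            ci_hi_raw=hi_raw,
        )
    resid = np.asarray(fit.resid)
    shapiro_p = float(stats.shapiro(resid).pvalue) if 3 <= n <= 5000 else float("nan")
    high = [t for t in predictors if vifs[t] >= VIF_LIMIT]
    return RegressionResult(
        outcome=outcome,
        terms=terms,
        adjusted_r2=float(fit.rsquared_adj),
        model_p=float(fit.f_pvalue),
        n=int(n),
        residual_normality_p=shapiro_p,
        high_vif_terms=high,
    )


def simple_models(
    data: pd.DataFrame,
    outcomes: Sequence[str],
    tissue_class: str = "wm",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    site_col: str | None = "site",
) -> pd.DataFrame:
    """One single-MR-variable model per (MR variable, outcome) pair.

    Returns a tidy screen with columns ``category, variable, tissue_class,
    outcome, standardized_beta, p_value, ci_lo, ci_hi, n`` suitable for
    :func:`select_variables`.
    """
    rows = []
    categories = dict(MR_CATEGORIES)
    categories["dti"] = dti_variables(tissue_class)
    for outcome in outcomes:
        for category, variables in categories.items():
            for var in variables:
                res = standardized_linear_model(
                    data, outcome, [var], covariates=covariates, site_col=site_col
                )
                est = res.term(var)
                rows.append(
                    {
                        "category": category,
                        "variable": var,
                        "tissue_class": tissue_class if category == "dti" else "",
                        "outcome": outcome,
                        "standardized_beta": est.beta,
                        "p_value": est.p_value,
                        "ci_lo": est.ci_lo,
                        "ci_hi": est.ci_hi,
                        "n": res.n,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SelectionResult:
    outcome: str
    tissue_class: str
    nbv_variable: str
    dti_variable: str


def _pick(block: pd.DataFrame) -> str:
    """Minimum p; exact p tie -> max |beta|; residual tie -> name order."""
    block = block.copy()
    block["abs_beta"] = block["standardized_beta"].abs()
    block = block.sort_values(
        by=["p_value", "abs_beta", "variable"], ascending=[True, False, True]
    )
    return str(block.iloc[0]["variable"])


def select_variables(
    screen: pd.DataFrame, outcome: str, tissue_class: str = "wm"
) -> SelectionResult:
    """Apply the most-significant-per-type rule to a Simple-model screen."""
    rows = screen[screen["outcome"] == outcome]
    nbv_block = rows[rows["category"] == "nbv"]
    dti_block = rows[(rows["category"] == "dti") & (rows["tissue_class"] == tissue_class)]
    if nbv_block.empty or dti_block.empty:
        raise SampleSizeError(
            f"screen incomplete for outcome {outcome!r} / tissue class {tissue_class!r}"
        )
    return SelectionResult(
        outcome=outcome,
        tissue_class=tissue_class,
        nbv_variable=_pick(nbv_block),
        dti_variable=_pick(dti_block),
    )


def complex_models(
    data: pd.DataFrame,
    selections: Dict[str, SelectionResult],
    outcomes: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    site_col: str | None = "site",
) -> Dict[str, RegressionResult]:
    """Fit one Complex model per outcome with the four selected MR predictors."""
    results: Dict[str, RegressionResult] = {}
    for outcome in outcomes:
        sel = selections[outcome]
        predictors = [
            sel.nbv_variable,
            "wmh_lesion_load",
            "lacune_count",
            sel.dti_variable,
        ]
        results[outcome] = standardized_linear_model(
            data, outcome, predictors, covariates=covariates, site_col=site_col
        )
    return results


def complex_results_table(results: Dict[str, RegressionResult]) -> pd.DataFrame:
    """Flatten Complex-model results into a publication-shaped tidy table."""
    rows = []
    for outcome, res in results.items():
        for t, est in res.terms.items():
            rows.append(
                {
                    "outcome": outcome,
                    "term": t,
                    "standardized_beta": est.beta,
                    "p_value": est.p_value,
                    "ci_lo": est.ci_lo,
                    "ci_hi": est.ci_hi,
                    "vif": est.vif,
                    "adjusted_r2": res.adjusted_r2,
                    "model_p": res.model_p,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)
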