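"""Site-level heterogeneity: between-site tests, per-site refits, slope labels.

Multicentre imaging pools data from different scanners; these analyses ask
whether the pooled associations are carried by all sites or driven by a few.
Between-site location tests (one-way ANOVA and Kruskal-Wallis) compare a
marker or outcome across sites; the Complex model is refit within individual
sites (without site terms); and each site's slope is labelled against the
pooled 95% CI — 'good' inside the interval, 'strong' outside it on the
steeper side of the pooled slope, 'weak' outside on the flatter side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SampleSizeError
from .models import (
    DEFAULT_COVARIATES,
    RegressionResult,
    SelectionResult,
    standardized_linear_model,
)

#: Per-site refits require at least this many subjects beyond the model terms.
MIN_EXTRA_N = 3


def between_site_tests(
    values: Sequence[float], site_labels: Sequence
) -> Tuple[float, float]:
    """One-way ANOVA p and Kruskal-Wallis p for a metric across sites."""
    df = pd.DataFrame({"value": values, "site": site_labels}).dropna()
    groups = [g["value"].to_numpy() for _, g in df.groupby("site")]
    if len(groups) < 2:
        raise SampleSizeError("between-site tests need at least two sites")
    small = [len(g) for g in groups if len(g) < 2]
    if small:
        raise SampleSizeError(
            "every site needs at least two subjects; exclude smaller sites first"
        )
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        return 1.0, 1.0  # identical site vectors: no between-site variation
    anova = stats.f_oneway(*groups)
    kruskal = stats.kruskal(*groups)
    return float(anova.pvalue), float(kruskal.pvalue)


def per_site_complex(
    data: pd.DataFrame,
    site_id,
    selection: SelectionResult,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    site_col: str = "site",
) -> RegressionResult:
    """Refit the Complex model within one site (no site indicator terms)."""
    sub = data[data[site_col] == site_id]
    predictors = [
        selection.nbv_variable,
        "wmh_lesion_load",
        "lacune_count",
        selection.dti_variable,
    ]
    n_terms = len(predictors) + len(covariates) + 1  # + intercept
    n = len(sub[[selection.outcome] + predictors + list(covariates)].dropna())
    if n < n_terms + MIN_EXTRA_N:
        raise SampleSizeError(
            f"site {site_id} has n={n}; refitting needs at least {n_terms + MIN_EXTRA_N}"
        )
    return standardized_linear_model(
        sub, selection.outcome, predictors, covariates=covariates, site_col=None
    )


@dataclass
class SiteFitClassification:
    site_id: object
    slope: float
    pooled_slope: float
    pooled_ci_lo: float
    pooled_ci_hi: float
    label: str  # good | strong | weak


def classify_site_fits(
    site_slopes: Dict[object, float],
    pooled_slope: float,
    pooled_ci: Tuple[float, float],
) -> List[SiteFitClassification]:
    """Label each site slope against the pooled 95% CI.

    Outside the interval, 'strong' means steeper than the pooled association
    (further from zero in the pooled direction) and 'weak' means flatter;
    the sides swap for negative pooled slopes.
    """
    lo, hi = pooled_ci
    out = []
    for site, slope in site_slopes.items():
        if lo <= slope <= hi:
            label = "good"
        elif pooled_slope >= 0:
            label = "strong" if slope > hi else "weak"
        else:
            label = "strong" if slope < lo else "weak"
        out.append(
            SiteFitClassification(
                site_id=site,
                slope=float(slope),
                pooled_slope=float(pooled_slope),
                pooled_ci_lo=float(lo),
                pooled_ci_hi=float(hi),
                label=label,
            )
        )
    return out


def site_scatter_plot(
    data: pd.DataFrame,
    x: str,
    y: str,
    pooled_result: RegressionResult,
    site_col: str = "site",
    path: str | None = None,
):
    """Scatter of ``y`` vs ``x`` with per-site regression lines and the pooled
    line plus its 95% CI band (on the unstandardized scale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = data[[x, y, site_col]].dropna()
    fig, ax = plt.subplots(figsize=(6, 4.5))
    xs = np.linspace(df[x].min(), df[x].max(), 50)
    for site, g in df.groupby(site_col):
        ax.scatter(g[x], g[y], s=12, alpha=0.6, label=f"site {site}")
        if len(g) >= 3:
            b, a = np.polyfit(g[x], g[y], 1)
            ax.plot(xs, a + b * xs, lw=1)
    slope, intercept, *_ = stats.linregress(df[x], df[y])
    est = pooled_result.term(x)
    sd_ratio = df[y].std(ddof=1) / df[x].std(ddof=1)  # back to the raw-unit scale
    xbar, ybar = df[x].mean(), df[y].mean()
    ax.plot(xs, intercept + slope * xs, "k--", lw=2, label="pooled")
    ax.fill_between(
        xs,
        ybar + est.ci_lo * sd_ratio * (xs - xbar),
        ybar + est.ci_hi * sd_ratio * (xs - xbar),
        color="k",
        alpha=0.08,
    )
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
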