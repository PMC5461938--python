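"""Site-level heterogeneity: between-site tests and slope classification.

Multicentre cohorts pool different scanners.  These analyses check whether
the DTI markers differ between sites (one-way ANOVA / Kruskal-Wallis) and
whether each site's own regression slope is consistent with the pooled 95%
CI ('good'), steeper ('strong') or flatter ('weak').
"""

from svdmarkers import (
    between_site_tests,
    classify_site_fits,
    per_site_complex,
    select_variables,
    simple_models,
)
from svdmarkers.errors import SampleSizeError
from svdmarkers.models import complex_models
from svdmarkers.synthetic import generate_analysis_cohort

df = generate_analysis_cohort(n=320, seed=23, true_beta=0.35, n_sites=4)

anova_p, kruskal_p = between_site_tests(df["fa_median_wm"], df["site"])
print(f"between-site comparison of the all-WM FA median: ANOVA p={anova_p:.3f}, "
      f"Kruskal-Wallis p={kruskal_p:.3f}")
print("large p: no evidence the sites' DTI distributions differ (homogeneous generator).")

outcome = "global_cognition"
screen = simple_models(df, [outcome], tissue_class="wm")
sel = select_variables(screen, outcome, "wm")
pooled = complex_models(df, {outcome: sel}, [outcome])[outcome]
est = pooled.term(sel.dti_variable)
print(f"\npooled Complex-model DTI slope: beta={est.beta:.3f} "
      f"CI [{est.ci_lo:.3f}, {est.ci_hi:.3f}]")

slopes = {}
for site in sorted(df["site"].unique()):
    try:
        r = per_site_complex(df, site, sel)
        slopes[site] = r.term(sel.dti_variable).beta
    except SampleSizeError as e:
        print(f"  site {site}: skipped ({e})")

print("\nper-site slopes vs the pooled 95% CI:")
for c in classify_site_fits(slopes, est.beta, (est.ci_lo, est.ci_hi)):
    print(f"  site {c.site_id}: slope {c.slope:6.3f} -> {c.label}")
print(
    "sites labelled 'good' are consistent with the pooled association; with"
    "\nfour equal sites roughly a quarter fall outside by sampling alone."
)
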