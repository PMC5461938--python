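"""Simple-model screen, variable selection and the Complex model.

The Simple models regress each MR variable separately on an outcome
(controlling age, sex, premorbid IQ, stratified by site).  Per outcome the
most significant NBV variant and DTI metric are selected (p ties broken by
the larger |standardized beta|), then the Complex model fits the four MR
predictors together to ask which carry independent information.
"""

from svdmarkers import complex_models, select_variables, simple_models
from svdmarkers.datasets import example_simple_screen
from svdmarkers.synthetic import generate_analysis_cohort

# 1. the selection rule on a published-style screen (standardized betas, p)
screen = example_simple_screen()
sel = select_variables(screen, "global_cognition", tissue_class="wm")
print("selection on the example screen, Global cognition:")
print(f"  NBV variant chosen: {sel.nbv_variable} (minimum p among whole/GM/WM NBV)")
print(f"  DTI metric chosen:  {sel.dti_variable} (p tie vs MD peak height, larger |beta|)")

# 2. the full Simple -> Complex chain on a synthetic cohort with known truth
df = generate_analysis_cohort(n=600, seed=17, true_beta=0.35, n_sites=3)
outcomes = ["global_cognition"]
my_screen = simple_models(df, outcomes, tissue_class="wm")
my_sel = {o: select_variables(my_screen, o, "wm") for o in outcomes}
results = complex_models(df, my_sel, outcomes)
res = results["global_cognition"]

print(f"\nComplex model for Global cognition (n={res.n}, adj R^2={res.adjusted_r2:.2f}):")
for term in (my_sel["global_cognition"].nbv_variable, "wmh_lesion_load",
             "lacune_count", my_sel["global_cognition"].dti_variable):
    est = res.term(term)
    print(
        f"  {term:18s} beta {est.beta:6.3f}  p {est.p_value:7.4f} "
        f" CI [{est.ci_lo:6.3f}, {est.ci_hi:6.3f}]  VIF {est.vif:.2f}"
    )
print(
    "\nthe DTI metric keeps a significant standardized beta (true effect 0.35)"
    "\nwhile WMH lesion load, which shares the same latent driver, does not"
    "\nadd independent signal; VIFs below 3 indicate acceptable collinearity."
)
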