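"""Generate a small synthetic multicentre SVD cohort and write it to disk.

Each subject gets a nested-ellipsoid brain phantom (FA/MD maps, tissue
probability maps, a WMH lesion mask), demographics, raw cognitive task
scores with realistic missingness, and a hidden 'latent integrity' scalar
that drives both the imaging degradation and the cognitive outcomes.
"""

import dataclasses

from svdmarkers import GeneratorConfig, SiteSpec, generate_cohort, write_cohort

config = dataclasses.replace(
    GeneratorConfig(seed=7),
    sites=(SiteSpec(1, 6), SiteSpec(2, 4, fa_offset=0.005, md_offset=1e-5)),
)
bundle = generate_cohort(config)
out = write_cohort(bundle, "example_cohort")

print(f"wrote {len(bundle.subjects)} subjects to {out}/")
print("\nper-site counts:")
print(bundle.cohort["site"].value_counts().to_string())
print("\nfirst subjects (site, age, lacunes, MoCA):")
print(bundle.cohort[["site", "age", "lacune_count", "moca"]].head(4).round(1).to_string())
print(
    "\nground truth (kept separate from analysis inputs): latent integrity per"
    " subject and the true standardized effect sizes; lower integrity means"
    " more WMH voxels and worse cognition."
)
print(bundle.ground_truth[["latent_integrity", "wmh_voxels"]].head(4).round(2).to_string())
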