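"""Compute the DTI histogram markers and volumetrics for one subject.

The chain is: hard tissue segmentation (argmax of the tissue probability
maps, lesion voxels overridden to WMH) -> NAWM and all-WM masks -> voxel
cleaning (MD > 0.0026 mm^2/s or FA > 1 removed) -> normalized 1000-bin
histograms -> median, peak height and peak value for FA and MD in each
tissue class, plus normalized brain volumes and WMH lesion load.
"""

import numpy as np

from svdmarkers import (
    GeneratorConfig,
    SiteSpec,
    generate_subject_imaging,
    hard_segment,
    make_masks,
    summarize_subject,
    summarize_subject_volumes,
)

config = GeneratorConfig(seed=3)
subject = generate_subject_imaging(
    integrity=-1.0,  # one SD below average white-matter integrity
    site=SiteSpec(1, 1),
    config=config,
    rng=np.random.default_rng(3),
)

labels = hard_segment(subject.tpm_gm, subject.tpm_wm, subject.tpm_csf, subject.wmh_mask)
masks = make_masks(labels)
summary = summarize_subject(subject.fa, subject.md, masks)
volumes = summarize_subject_volumes(subject)

print("histogram markers (NAWM vs all-WM; MD on the x1e-3 mm^2/s scale):")
for metric, scale in (("fa", 1), ("md", 1e3)):
    for stat in ("median", "peak_height", "peak_value"):
        s = 1 if stat == "peak_height" else scale
        nawm = summary.metrics[("nawm", metric, stat)] * s
        wm = summary.metrics[("wm", metric, stat)] * s
        print(f"  {metric.upper():2s} {stat:12s}  NAWM {nawm:8.4f}   WM {wm:8.4f}")
print(
    "\nincluding the lesion voxels (all-WM) lowers the FA median and broadens"
    "\nboth distributions relative to NAWM - the damaged-tissue signature."
)
print(
    f"\nvolumetrics: whole NBV {volumes.whole_nbv_ml:.1f} ml "
    f"(GM {volumes.gm_nbv_ml:.1f} + WM {volumes.wm_nbv_ml:.1f}), "
    f"WMH {volumes.wmh_ml:.2f} ml = {volumes.wmh_lesion_load_pct:.2f}% lesion load, "
    f"{volumes.lacune_count} lacunes"
)
print(f"voxels removed by cleaning (all-WM): MD rule {summary.n_removed_md['wm']}, "
      f"FA rule {summary.n_removed_fa['wm']}")
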