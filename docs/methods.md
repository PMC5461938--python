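# Methods

This note documents the models and procedures the package implements, the
design choices made where the design was genuinely open, and what the
synthetic validation does and does not demonstrate about real data.

## Imaging markers

**Hard segmentation.** Each voxel is assigned to the tissue class (GM, WM,
CSF) with the highest probability in the coregistered tissue probability
maps; voxels inside the binary WMH mask are then overridden to a dedicated
WMH label. Probability ties are broken by the fixed priority GM > WM > CSF —
ties are measure-zero on real probability maps, so any deterministic rule
serves; this one is declared so the operation is testable. Voxels where all
three probabilities fall below 0.01 are background (real pipelines use a
brain mask; the generator provides exact anatomy, so a threshold suffices).

**Analysis masks.** NAWM = WM-labelled voxels; all-WM = WM ∪ WMH. The all-WM
mask needs no lesion contouring downstream of segmentation, which is why the
comparison between the two tissue classes matters practically.

**Voxel cleaning.** Within a mask, voxels with MD > 0.0026 mm²/s (probable
CSF partial volume) or FA > 1 (spurious tensor fits) are removed before
histogramming; both inequalities are strict, read literally from the rule's
phrasing ("above"). By default a voxel failing either rule leaves *both* the
FA and MD collections so the two histograms share one voxel support; whether
the rules should instead apply independently is not determinable from the
method description, so the independent variant is available via
`clean_dti_voxels(..., joint=False)`.

**Histograms.** Fixed-range normalized histograms with 1000 bins: FA on
[0, 1] (width 0.001), MD on [0, 4×10⁻³] mm²/s (width 4×10⁻⁶, i.e. 0.004 on
the ×10⁻³ reporting scale). Bins are half-open with the final bin closed
(numpy's convention). Markers: median (center of the first bin where the
cumulative proportion reaches 0.5), peak height (maximum proportion) and
peak value (center of the attaining bin, ties to the lowest bin). The median
is histogram-derived because the markers are defined as extracted *from the
histograms*; a voxel-level median is available (`median_from="voxels"`) and
differs by at most one bin width when the sample median is an order
statistic (odd n). For even n the sample median interpolates between two
order statistics, which the bin-center convention does not model — the
oracle tests therefore use odd sample sizes. MD is handled internally in
mm²/s; only reporting layers rescale to ×10⁻³, avoiding unit drift.

**Volumetrics.** Native GM/WM volumes integrate the soft segmentation
(Σ probability × voxel volume); the subject's skull-based scaling factor
(an input — its estimation is out of scope) converts them to normalized
brain volumes. The normalized GM volume inside the WMH mask is reassigned
from GM to WM, conserving the whole-brain sum exactly, because
intensity-driven segmentation misclassifies lesions as GM. WMH volume is the
binary mask times voxel volume (the lesion mask is a hard contour). Lesion
load = 100 × WMH volume / whole brain volume, with the *native*
soft-segmentation brain volume as the default denominator (the load is
defined before normalization is introduced); a flag switches to the
normalized denominator. Lacune counts are inputs — identification is a
visual rating, not an algorithm.

## Cognition

Seven tasks map to four domains (Processing speed: DSC + TMT-A; Mental
flexibility: TMT-B; Verbal fluency: FAS + animals; Verbal memory: RAVLT
immediate + delayed). Raw scores are z-transformed against age-banded norms;
timed tasks are sign-flipped at the transform so every composite is
higher-is-better. Two missingness mechanisms:

* *unable to complete* → the task receives the lowest available z-score,
  interpreted as the cohort-wide minimum observed z for that task (a literal
  reading of "available"; the subject's-own-minimum variant is behind
  `strategy="subject_min"`);
* *other reasons* → the domain composite is computed without that task.

Global cognition is the mean of the four domains and is missing if any
domain is. MoCA, SSQoL and EuroQoL are analysed as raw scores. Impairment is
tested per domain by a two-sided one-sample t-test against zero.

**Exclusion ledger.** The cascade is: sites recruiting a single subject are
dropped (a one-subject stratum cannot be site-stratified); subjects with
failed MRI acquisition are dropped; subjects missing premorbid IQ are
dropped from *all* models, because it is a covariate in every model;
subjects missing an outcome are dropped from that outcome's models only.
On the example enrolment (48/29/14/11/6/1 across six sites, two MRI failures
at site 1 and four at site 4, one subject missing Verbal fluency, one
missing Verbal memory + premorbid IQ, one missing premorbid IQ only) this
yields 102 subjects with complete imaging, 99 for Verbal fluency and 100 for
every other outcome — the covariate interpretation is what makes the n drop
by two rather than three for non-fluency outcomes.

## Regression layer

All models are OLS with age, sex and premorbid IQ as covariates and site
stratification implemented as fixed-effect site indicators (reference =
first site) — pooled coefficients are reported per model, so indicator
adjustment rather than per-stratum fitting is the appropriate reading;
per-site refits live in the site-heterogeneity module. Standardized
β = b·sd(x)/sd(y) over the analysis sample, with the 95 % CI scaled by the
same factor; site indicators and sex (a 0/1 indicator) are reported
unstandardized, and raw-scale coefficients/CIs are always carried alongside.
VIF_j = 1/(1−R²_j) from regressing term j on all other design columns;
Complex models flag any VIF ≥ 3. Residual normality is assessed by
Shapiro–Wilk. No multiple-testing correction is applied anywhere — p-values
are reported uncorrected, deliberately.

**Selection rule.** Per outcome and category (NBV variants; DTI metrics
within a tissue class): minimum p; exact p ties go to the larger |β|;
residual ties to name order, making the rule total, deterministic and
row-order invariant. On the bundled example screen this selects whole NBV
and (via a p tie at 0.001 resolved by |β|: 0.371 vs 0.303) the all-WM FA
median for Global cognition.

**Site heterogeneity.** Between-site location tests use one-way ANOVA and
Kruskal–Wallis. Per-site Complex refits require n ≥ model terms + 3. Site
slopes are classified against the pooled 95 % CI on the slope coefficient —
'good' inside, 'strong' outside on the steeper side of the pooled direction,
'weak' on the flatter side. This operationalises what is otherwise a visual
judgement of regression lines; the slope determines flat versus steep, but
it is an approximation of a figure-based call, not a claim about any
particular rater's procedure. For k equal-sized homogeneous sites the
expected 'good' fraction is 2Φ(1.96/√(k−1))−1 (≈ 0.74 for k = 4), *not* 95 %:
a site estimate deviates from the pooled one with SD √(k−1) times the pooled
SE. The property test asserts the simulation matches this closed form.

## Synthetic cohort generator

**What it emulates.** A six-site cohort with the enrolment imbalance of a
realistic multicentre SVD trial (48/29/14/11/6/1 by default), severe-SVD
marker magnitudes, and the latent structure the analysis is meant to detect:
one standardized white-matter-integrity scalar per subject drives (a) the
NAWM/WMH FA and MD means (slopes 0.02 FA and −4×10⁻⁵ mm²/s per SD), (b) the
WMH lesion load — lognormal with mean 3.4 % and SD 2.2 % of brain volume,
log-scale loading −0.35 per SD of integrity, (c) lacune counts — Poisson
with rate 4.4·exp(−0.35·integrity), correlated with lesion burden through
the shared driver without being a deterministic function of it, and (d) the
cognitive outcomes, outcome_z = β·integrity + covariate effects + noise,
with default true standardized βs of 0.17–0.38 across outcomes and residual
SD chosen so each outcome has unit variance. Site effects are additive FA/MD
offsets (scanner-like), not cognitive effects.

**Anatomy.** Nested ellipsoids (WM core to normalized radius 0.55, GM rind
to 0.80, CSF shell to 0.95) with logistic band softening; the three
probabilities are normalized to sum exactly to 1 in-brain. WMH blobs are
grown around random seeds within WM-dominant voxels until the subject's
target lesion volume is met. Voxel values are truncated normals per tissue
(GM FA 0.15 ± 0.07, NAWM 0.35 ± 0.12, CSF 0.10 ± 0.08, WMH 0.22 ± 0.12; MD
0.85/0.77/2.9/1.05 ×10⁻³ ± 0.12/0.11/0.40/0.20 ×10⁻³ mm²/s) — truncation
rather than clipping, so no artefactual point mass accumulates at the
support edges. The CSF MD tail crosses the 0.0026 mm²/s cleaning threshold
and a small fraction (0.002) of in-brain voxels gets spurious FA in (1, 1.2],
so both cleaning rules fire with nonzero frequency. These distributions were
chosen once to land the white-matter histogram markers in the severe-SVD
range (WM FA median ≈ 0.33, FA peak height ≈ 3×10⁻³, MD peak height
≈ 1.4×10⁻², lesion load ≈ 3.4 %) and are not otherwise calibrated.

**Cognition.** Domain-level outcome scores generate task z-scores with an
impairment shift of −0.8 (the patient group scores below age norms) plus
task noise (SD 0.3); raw scores are recovered through the same synthetic
age-banded normative table used for the forward transform. Timed tasks are
emitted on their raw higher-is-worse scale. Each task is independently
flagged 'unable' (p = 0.02) or 'other' (p = 0.005). MoCA is an integer on
0–30, SSQoL on 49–245, EuroQoL on 0–100.

**Reproducibility.** All randomness flows from one seed through
per-subject spawned RNG streams, so bundles are bit-identical per
config+seed and per-site subsets reproduce independently.

**The tabular calibration generator.** Parameter recovery, CI coverage,
null calibration and the mediation pattern are studied on
`generate_analysis_cohort`, which draws the subject-level analysis table
directly: the all-WM FA median is an affine readout of integrity (exact by
default, so the true standardized coefficient is exactly the configured β),
WMH load and lacunes are noisy monotone functions of the same integrity, and
the outcome has unit variance by construction. Voxelwise phantoms at
200 replicates × n = 500 would add nothing to these purely statistical
questions; the voxel generator is exercised where voxels matter
(segmentation, histograms, volumetrics, contamination direction, the
end-to-end pipeline). In the noiseless linearity check the *raw* slope of
the outcome on integrity equals the configured effect (with zero residual
noise the outcome SD collapses to β·sd(x), so the standardized coefficient
is identically 1 — the raw scale is the meaningful one there).

## What the validation does and does not show

Passing tests demonstrate that the pipeline recovers known standardized
effects without bias (mean recovered β within ±0.03 of 0.30 at n = 500 over
200 replicates; empirical 95 % CI coverage within [0.92, 0.98]), that null
effects produce uniform p-values, that the Complex model separates a clean
DTI readout from a noisy WMH correlate of the same latent cause, and that
every deterministic operation matches independent oracles. They do not show
that real multicentre DTI behaves like the phantom: there is no registration
error, no spatially correlated noise, no scanner-specific distortion beyond
additive offsets, no realistic lesion morphology, and the normative table is
synthetic. Absolute volumes are phantom-scale (tens of ml).

One finite-sample caveat is intrinsic, not an artefact: the per-subject FA
*peak height* comparison between NAWM and all-WM is noise-limited. The
real-data NAWM→WM peak-height decrement is on the order of 1 %, implying
strong overlap between lesion and NAWM FA densities at the mode; for small
lesions the expected decrement is then smaller than the Poisson noise of bin
counts at any practical voxel count, so the contamination direction for FA
peak height holds in cohort means but not deterministically per subject.
FA median and MD peak height decrease per subject with wide margins, and are
asserted as such.

## Problem sizes

Default grids are 32³ voxels of 2 mm (the contamination and
marker-magnitude checks use 64³); calibration studies use 200 replicates at
n = 500; oracle sweeps use 100–200 random instances. These sizes put every
quantity's simulation error well inside its assertion band while keeping the
whole suite in the tens of seconds.
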