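"""Synthetic multicentre SVD cohort generator with known ground truth.

Two generators share one latent-variable structure:

* :func:`generate_cohort` builds full voxelwise subjects — a nested-ellipsoid
  phantom (WM core, GM rind, CSF shell) with WMH blobs placed in white
  matter, voxelwise FA/MD drawn from tissue-specific normal distributions
  plus per-site scanner offsets — together with demographics, raw cognitive
  task scores and the two missingness mechanisms ('unable' vs 'other').
* :func:`generate_analysis_cohort` builds the subject-level analysis table
  directly (no voxel data), with the DTI metric an exact affine readout of
  the latent integrity, for statistical calibration studies (parameter
  recovery, null calibration, mediation structure) at sample sizes where
  voxel phantoms would be wasteful.

A single standardized latent 'integrity' scalar per subject drives both the
imaging degradation (lower FA, higher MD, more WMH, more lacunes) and the
cognitive outcomes (outcome_z = beta * integrity + covariate effects +
noise), so the associations measured downstream exist by construction with
known standardized magnitude.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cognition import DOMAIN_TASKS, DOMAINS, NormativeTable, OTHER, TASKS, UNABLE
from .errors import ConfigError, GenerationError
from .images import SubjectImaging, VoxelVolume


@dataclass(frozen=True)
class SiteSpec:
    """One recruiting site: sample size plus additive scanner offsets."""

    site_id: int
    n_subjects: int
    fa_offset: float = 0.0  # dimensionless, added to every FA voxel
    md_offset: float = 0.0  # mm^2/s, added to every MD voxel


@dataclass(frozen=True)
class TissueDistribution:
    fa_mean: float
    fa_sd: float
    md_mean: float  # mm^2/s
    md_sd: float


def default_sites() -> Tuple[SiteSpec, ...]:
    """Six sites with the study-scale enrolment imbalance and small scanner offsets."""
    return (
        SiteSpec(1, 48, 0.0, 0.0),
        SiteSpec(2, 29, 0.005, 1.0e-5),
        SiteSpec(3, 14, -0.005, -1.0e-5),
        SiteSpec(4, 11, 0.010, 2.0e-5),
        SiteSpec(5, 6, -0.010, -2.0e-5),
        SiteSpec(6, 1, 0.0, 0.0),
    )


def default_tissue_means() -> Dict[str, TissueDistribution]:
    """Voxelwise FA/MD distributions chosen to give white-matter histogram
    markers of realistic magnitude (FA median ~0.34, MD peak height ~1.4e-2,
    FA peak height ~3.3e-3) and a CSF diffusivity tail crossing the cleaning
    threshold."""
    return {
        "gm": TissueDistribution(0.15, 0.07, 0.85e-3, 1.2e-4),
        "nawm": TissueDistribution(0.35, 0.12, 0.77e-3, 1.1e-4),
        "csf": TissueDistribution(0.10, 0.08, 2.9e-3, 4.0e-4),
        "wmh": TissueDistribution(0.22, 0.12, 1.05e-3, 2.0e-4),
    }


def default_true_betas() -> Dict[str, float]:
    """Standardized effect of latent integrity on each outcome (~0.17-0.38)."""
    return {
        "global_cognition": 0.37,
        "processing_speed": 0.28,
        "mental_flexibility": 0.35,
        "verbal_fluency": 0.38,
        "verbal_memory": 0.17,
        "moca": 0.33,
        "ssqol": 0.21,
        "euroqol": 0.27,
    }


DEFAULT_COVARIATE_EFFECTS = {"age": -0.15, "sex": 0.05, "premorbid_iq": 0.25}


@dataclass
class GeneratorConfig:
    seed: int = 0
    sites: Tuple[SiteSpec, ...] = field(default_factory=default_sites)
    grid_shape: Tuple[int, int, int] = (32, 32, 32)
    voxel_mm: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    tissue_means: Dict[str, TissueDistribution] = field(default_factory=default_tissue_means)
    # lesion model: lognormal load (% of brain volume), log-scale decrease
    # per SD of integrity
    wmh_load_mean_pct: float = 3.4
    wmh_load_sd_pct: float = 2.2
    wmh_integrity_loading: float = 0.35
    lacune_rate: float = 4.4  # expected count at the mean lesion load
    # integrity -> microstructure coupling (shift of the NAWM/WMH means per SD)
    integrity_fa_slope: float = 0.02
    integrity_md_slope: float = 4.0e-5
    spurious_fa_frac: float = 0.002  # fraction of in-brain voxels with FA in (1, 1.2]
    true_betas: Dict[str, float] = field(default_factory=default_true_betas)
    covariate_effects: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    noise_sd: Optional[Dict[str, float]] = None  # None -> unit outcome variance
    impairment_shift: float = -0.8  # mean task z of the patient group vs norms
    task_noise_sd: float = 0.3
    p_unable: float = 0.02
    p_other: float = 0.005
    scaling_factor_mean: float = 1.25
    scaling_factor_sd: float = 0.08
    mri_failure_rate: float = 0.0
    age_mean: float = 68.2
    age_sd: float = 9.1
    sex_p_male: float = 0.59
    iq_mean: float = 115.8
    iq_sd: float = 8.1

    def __post_init__(self) -> None:
        # accept plain sequences / dicts (e.g. parsed from YAML)
        self.sites = tuple(
            s if isinstance(s, SiteSpec) else SiteSpec(*s) for s in self.sites
        )
        self.tissue_means = {
            k: (v if isinstance(v, TissueDistribution) else TissueDistribution(**v))
            for k, v in self.tissue_means.items()
        }
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)

    def validate(self) -> None:
        for name in ("p_unable", "p_other", "sex_p_male", "mri_failure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for s in self.sites:
            if s.n_subjects < 0:
                raise ConfigError(f"sites: n_subjects must be >= 0 for site {s.site_id}")
        for key, t in self.tissue_means.items():
            if not 0.0 <= t.fa_mean <= 1.0:
                raise ConfigError(f"tissue_means[{key}].fa_mean must be in [0, 1]")
            if not 0.0 < t.md_mean < 4.0e-3:
                raise ConfigError(f"tissue_means[{key}].md_mean must be in (0, 4e-3) mm^2/s")
            if t.fa_sd < 0 or t.md_sd < 0:
                raise ConfigError(f"tissue_means[{key}] dispersions must be >= 0")
        if self.tissue_means["wmh"].fa_mean >= self.tissue_means["nawm"].fa_mean:
            raise ConfigError("tissue_means: WMH fa_mean must be below NAWM fa_mean")
        if self.tissue_means["wmh"].md_mean <= self.tissue_means["nawm"].md_mean:
            raise ConfigError("tissue_means: WMH md_mean must be above NAWM md_mean")
        for name in ("wmh_load_mean_pct", "wmh_load_sd_pct", "lacune_rate",
                     "task_noise_sd", "scaling_factor_sd", "age_sd", "iq_sd",
                     "spurious_fa_frac"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.scaling_factor_mean <= 0:
            raise ConfigError("scaling_factor_mean must be positive")
        unknown = set(self.true_betas) - set(
            ("global_cognition",) + DOMAINS + ("moca", "ssqol", "euroqol")
        )
        if unknown:
            raise ConfigError(f"true_betas has unknown outcomes {sorted(unknown)}")

    @property
    def total_n(self) -> int:
        return sum(s.n_subjects for s in self.sites)

    def residual_sd(self, outcome: str) -> float:
        """Residual SD per outcome; default makes the outcome unit-variance."""
        if self.noise_sd is not None and outcome in self.noise_sd:
            return float(self.noise_sd[outcome])
        beta = self.true_betas.get(outcome, 0.0)
        explained = beta**2 + sum(c**2 for c in self.covariate_effects.values())
        return float(np.sqrt(max(1.0 - explained, 0.0)))

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CohortBundle:
    subjects: List[SubjectImaging]
    cohort: pd.DataFrame  # analysis inputs: demographics, raw scores, flags
    ground_truth: pd.DataFrame  # latent variables; never an analysis input
    config: GeneratorConfig


def synthetic_normative_table() -> NormativeTable:
    """Age-banded synthetic norms consistent with the raw-score generator.

    Three bands (40-60, 60-75, 75-95).  TMT tasks are timed (higher raw is
    worse); all others are accuracy counts.
    """
    rows = []
    bands = ((40, 60), (60, 75), (75, 95))
    spec = {
        "dsc": ([55, 50, 45], 12, "higher_better"),
        "tmt_a": ([35, 42, 50], 14, "higher_worse"),
        "tmt_b": ([80, 95, 110], 35, "higher_worse"),
        "fas": ([41, 40, 38], 11, "higher_better"),
        "animals": ([20, 19, 17], 5.5, "higher_better"),
        "ravlt_imm": ([48, 44, 40], 10, "higher_better"),
        "ravlt_del": ([9.5, 8.5, 7.5], 3, "higher_better"),
    }
    for task, (means, sd, orientation) in spec.items():
        for (lo, hi), m in zip(bands, means):
            rows.append(
                {"task": task, "age_lo": lo, "age_hi": hi, "mean": m, "sd": sd,
                 "orientation": orientation}
            )
    return NormativeTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# voxelwise phantom
# ---------------------------------------------------------------------------

#: Normalized-radius band edges of the nested-ellipsoid phantom.
WM_EDGE, GM_EDGE, CSF_EDGE = 0.55, 0.80, 0.95
_BAND_SOFTNESS = 0.04


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return np.full(n, np.clip(mean, lo, hi))
    from scipy import stats

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _phantom_tpms(
    grid_shape: Tuple[int, int, int], rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(tpm_gm, tpm_wm, tpm_csf, brain_mask) for a nested-ellipsoid phantom."""
    if min(grid_shape) < 12:
        raise GenerationError(
            f"grid {grid_shape} too small to host WM/GM/CSF shells (need >= 12 per axis)"
        )
    center = [(s - 1) / 2 + rng.uniform(-0.5, 0.5) for s in grid_shape]
    semi = [s * 0.48 for s in grid_shape]
    coords = np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij")
    r = np.sqrt(sum(((c - m) / a) ** 2 for c, m, a in zip(coords, center, semi)))

    def inside(edge: float) -> np.ndarray:
        return 1.0 / (1.0 + np.exp((r - edge) / _BAND_SOFTNESS))

    wm_w = inside(WM_EDGE)
    gm_w = inside(GM_EDGE) - wm_w
    csf_w = inside(CSF_EDGE) - inside(GM_EDGE)
    brain = r < CSF_EDGE
    total = gm_w + wm_w + csf_w
    tpm_gm = np.where(brain, gm_w / total, 0.0)
    tpm_wm = np.where(brain, wm_w / total, 0.0)
    tpm_csf = np.where(brain, csf_w / total, 0.0)
    return tpm_gm, tpm_wm, tpm_csf, brain


def _place_wmh(
    tpm_gm: np.ndarray,
    tpm_wm: np.ndarray,
    tpm_csf: np.ndarray,
    n_lesion_vox: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Blob-shaped lesion mask confined to WM-dominant voxels."""
    mask = np.zeros(tpm_wm.shape)
    if n_lesion_vox <= 0:
        return mask
    dominant_wm = (tpm_wm > tpm_gm) & (tpm_wm > tpm_csf) & (tpm_wm > 0)
    wm_idx = np.argwhere(dominant_wm)
    if len(wm_idx) == 0:
        raise GenerationError("phantom has no WM-dominant voxels to host lesions")
    n_lesion_vox = min(n_lesion_vox, int(0.6 * len(wm_idx)))
    n_blobs = max(1, int(round(n_lesion_vox / 40)))
    centers = wm_idx[rng.choice(len(wm_idx), size=n_blobs, replace=False)]
    d2 = np.min(
        ((wm_idx[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    ).astype(float)
    d2 += rng.uniform(0, 0.5, size=d2.shape)  # jitter breaks distance ties
    chosen = wm_idx[np.argsort(d2)[:n_lesion_vox]]
    mask[tuple(chosen.T)] = 1.0
    return mask


def generate_subject_imaging(
    integrity: float,
    site: SiteSpec,
    config: GeneratorConfig,
    rng: np.random.Generator,
    subject_id: str = "S000",
) -> SubjectImaging:
    """One subject's phantom volumes given the latent integrity scalar."""
    if not np.isfinite(integrity):
        raise GenerationError("integrity must be finite")
    tpm_gm, tpm_wm, tpm_csf, brain = _phantom_tpms(config.grid_shape, rng)
    voxel_ml = float(np.prod(config.voxel_mm)) / 1000.0
    brain_ml = float((tpm_gm + tpm_wm).sum() * voxel_ml)

    # lesion load (% of brain volume): lognormal, decreasing in integrity
    if config.wmh_load_mean_pct > 0:
        cv2 = (config.wmh_load_sd_pct / config.wmh_load_mean_pct) ** 2
        sigma = np.sqrt(np.log1p(cv2))
        mu = np.log(config.wmh_load_mean_pct) - 0.5 * sigma**2
        load_pct = float(
            np.exp(mu - config.wmh_integrity_loading * integrity + sigma * rng.standard_normal())
        )
    else:
        load_pct = 0.0
    n_lesion_vox = int(round(load_pct / 100.0 * brain_ml / voxel_ml))
    wmh = _place_wmh(tpm_gm, tpm_wm, tpm_csf, n_lesion_vox, rng)

    labels = np.zeros(config.grid_shape, dtype=np.int8)  # 0 bg, 1 gm, 2 wm, 3 csf, 4 wmh
    stacked = np.stack([tpm_gm, tpm_wm, tpm_csf])
    labels[brain] = (np.argmax(stacked, axis=0) + 1)[brain]
    labels[wmh == 1] = 4

    fa = np.zeros(config.grid_shape)
    md = np.zeros(config.grid_shape)
    tissue_for_label = {1: "gm", 2: "nawm", 3: "csf", 4: "wmh"}
    for lab, tissue in tissue_for_label.items():
        sel = labels == lab
        n = int(sel.sum())
        if n == 0:
            continue
        dist = config.tissue_means[tissue]
        fa_mean, md_mean = dist.fa_mean, dist.md_mean
        if tissue in ("nawm", "wmh"):  # microstructure tracks integrity
            fa_mean = fa_mean + config.integrity_fa_slope * integrity
            md_mean = md_mean - config.integrity_md_slope * integrity
        # truncated normals: physical supports without boundary point masses
        fa[sel] = _truncated_normal(
            fa_mean + site.fa_offset, dist.fa_sd, 0.0, 1.2, n, rng
        )
        md[sel] = _truncated_normal(
            md_mean + site.md_offset, dist.md_sd, 1e-6, 3.999e-3, n, rng
        )
    if config.spurious_fa_frac > 0:
        in_brain = np.argwhere(brain)
        n_spur = rng.binomial(len(in_brain), config.spurious_fa_frac)
        if n_spur > 0:
            pick = in_brain[rng.choice(len(in_brain), size=n_spur, replace=False)]
            fa[tuple(pick.T)] = rng.uniform(1.0, 1.2, size=n_spur)

    # lacunes share the latent driver with the lesion load (correlated burden
    # markers) without being a deterministic function of it
    lacune_lambda = config.lacune_rate * np.exp(-config.wmh_integrity_loading * integrity)
    lacunes = int(rng.poisson(lacune_lambda))
    scaling = float(
        max(0.5, rng.normal(config.scaling_factor_mean, config.scaling_factor_sd))
    )
    vx = config.voxel_mm
    return SubjectImaging(
        subject_id=subject_id,
        site_id=site.site_id,
        fa=VoxelVolume(fa, vx, "FA"),
        md=VoxelVolume(md, vx, "MD"),
        tpm_gm=VoxelVolume(tpm_gm, vx, "TPM"),
        tpm_wm=VoxelVolume(tpm_wm, vx, "TPM"),
        tpm_csf=VoxelVolume(tpm_csf, vx, "TPM"),
        wmh_mask=VoxelVolume(wmh, vx, "mask"),
        lacune_count=lacunes,
        scaling_factor=scaling,
        latent_integrity=float(integrity),
    )


# ---------------------------------------------------------------------------
# cognition
# ---------------------------------------------------------------------------


def generate_cognition(
    integrity: float,
    demographics: Dict[str, float],
    config: GeneratorConfig,
    rng: np.random.Generator,
    norms: NormativeTable | None = None,
) -> Dict[str, object]:
    """Raw task scores, missingness codes and questionnaire totals for one subject.

    ``demographics`` must provide ``age``, ``sex`` (0/1) and ``premorbid_iq``.
    Timed tasks are emitted on their raw higher-is-worse scale.
    """
    for key in ("age", "sex", "premorbid_iq"):
        if key not in demographics or pd.isna(demographics[key]):
            raise ConfigError(f"demographics missing {key!r}")
    norms = norms or synthetic_normative_table()
    z_age = (demographics["age"] - config.age_mean) / config.age_sd
    p = config.sex_p_male
    z_sex = (demographics["sex"] - p) / np.sqrt(p * (1 - p))
    z_iq = (demographics["premorbid_iq"] - config.iq_mean) / config.iq_sd
    cov = config.covariate_effects
    cov_part = cov["age"] * z_age + cov["sex"] * z_sex + cov["premorbid_iq"] * z_iq

    out: Dict[str, object] = {}
    domain_z: Dict[str, float] = {}
    for outcome in DOMAINS:
        beta = config.true_betas.get(outcome, 0.0)
        domain_z[outcome] = float(
            beta * integrity + cov_part + config.residual_sd(outcome) * rng.standard_normal()
        )
    for domain, members in DOMAIN_TASKS.items():
        for task in members:
            task_z = (
                config.impairment_shift
                + domain_z[domain]
                + config.task_noise_sd * rng.standard_normal()
            )
            mean, sd, orientation = norms.lookup(task, demographics["age"])
            raw = mean + task_z * sd if orientation == "higher_better" else mean - task_z * sd
            u = rng.uniform()
            if u < config.p_unable:
                out[task] = np.nan
                out[f"{task}_missing"] = UNABLE
            elif u < config.p_unable + config.p_other:
                out[task] = np.nan
                out[f"{task}_missing"] = OTHER
            else:
                out[task] = float(raw)
                out[f"{task}_missing"] = ""
    for outcome in ("moca", "ssqol", "euroqol"):
        beta = config.true_betas.get(outcome, 0.0)
        z = beta * integrity + cov_part + config.residual_sd(outcome) * rng.standard_normal()
        if outcome == "moca":
            out["moca"] = float(np.clip(np.round(24.9 + 3.5 * z), 0, 30))
        elif outcome == "ssqol":
            out["ssqol"] = float(np.clip(190.6 + 32.8 * z, 49, 245))
        else:
            out["euroqol"] = float(np.clip(69.3 + 19.1 * z, 0, 100))
    return out


def generate_cohort(config: GeneratorConfig) -> CohortBundle:
    """The full synthetic multicentre cohort (imaging + cognition + truth).

    Per-subject RNG streams are spawned from the single config seed, so the
    bundle is bit-identical for identical configs and per-site subsets are
    reproducible independently.
    """
    config.validate()
    if config.total_n < 1:
        raise ConfigError("sites: total n_subjects must be >= 1")
    norms = synthetic_normative_table()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.total_n)
    subjects: List[SubjectImaging] = []
    rows = []
    truth_rows = []
    k = 0
    for site in config.sites:
        for _ in range(site.n_subjects):
            rng = np.random.default_rng(streams[k])
            subject_id = f"S{k:03d}"
            integrity = float(rng.standard_normal())
            demo = {
                "age": float(np.clip(rng.normal(config.age_mean, config.age_sd), 40, 95)),
                "sex": int(rng.uniform() < config.sex_p_male),
                "premorbid_iq": float(rng.normal(config.iq_mean, config.iq_sd)),
            }
            subject = generate_subject_imaging(integrity, site, config, rng, subject_id)
            cognition = generate_cognition(integrity, demo, config, rng, norms)
            mri_fail = bool(rng.uniform() < config.mri_failure_rate)
            row = {
                "subject_id": subject_id,
                "site": site.site_id,
                "mri_fail": mri_fail,
                "lacune_count": subject.lacune_count,
                "scaling_factor": subject.scaling_factor,
                **demo,
                **cognition,
            }
            rows.append(row)
            truth_rows.append(
                {
                    "subject_id": subject_id,
                    "latent_integrity": integrity,
                    "wmh_voxels": int(subject.wmh_mask.values.sum()),
                }
            )
            subjects.append(subject)
            k += 1
    cohort = pd.DataFrame(rows).set_index("subject_id")
    truth = pd.DataFrame(truth_rows).set_index("subject_id")
    for outcome, beta in config.true_betas.items():
        truth[f"true_beta_{outcome}"] = beta
    return CohortBundle(subjects=subjects, cohort=cohort, ground_truth=truth, config=config)


def write_cohort(bundle: CohortBundle, directory: str | Path) -> Path:
    """Write NIfTI volumes, cohort CSV, ground-truth CSV and a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for subject in bundle.subjects:
        sdir = directory / subject.subject_id
        sdir.mkdir(exist_ok=True)
        for name in ("fa", "md", "tpm_gm", "tpm_wm", "tpm_csf", "wmh_mask"):
            getattr(subject, name).save(sdir / f"{name}.nii.gz")
    bundle.cohort.to_csv(directory / "cohort.csv")
    bundle.ground_truth.to_csv(directory / "ground_truth.csv")
    synthetic_normative_table().to_csv(directory / "normative_table.csv")
    manifest = {
        "seed": bundle.config.seed,
        "config_hash": bundle.config.content_hash(),
        "n_subjects": len(bundle.subjects),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def read_cohort(directory: str | Path) -> Tuple[List[SubjectImaging], pd.DataFrame]:
    """Load subjects and the cohort table written by :func:`write_cohort`."""
    directory = Path(directory)
    cohort_path = directory / "cohort.csv"
    if not cohort_path.exists():
        raise FileNotFoundError(f"missing cohort table: {cohort_path}")
    cohort = pd.read_csv(cohort_path, index_col="subject_id", keep_default_na=False,
                         na_values=[""])
    for task in TASKS:  # missingness codes are strings, empty = observed
        col = f"{task}_missing"
        if col in cohort.columns:
            cohort[col] = cohort[col].fillna("").astype(str)
    if "mri_fail" in cohort.columns:
        cohort["mri_fail"] = cohort["mri_fail"].map(
            {"True": True, "False": False, True: True, False: False}
        )
    subjects = []
    for subject_id, row in cohort.iterrows():
        sdir = directory / str(subject_id)
        vols = {
            name: VoxelVolume.from_nifti(sdir / f"{name}.nii.gz", kind)
            for name, kind in (
                ("fa", "FA"), ("md", "MD"), ("tpm_gm", "TPM"),
                ("tpm_wm", "TPM"), ("tpm_csf", "TPM"), ("wmh_mask", "mask"),
            )
        }
        subjects.append(
            SubjectImaging(
                subject_id=str(subject_id),
                site_id=int(row["site"]),
                lacune_count=int(row["lacune_count"]),
                scaling_factor=float(row["scaling_factor"]),
                **vols,
            )
        )
    return subjects, cohort


# ---------------------------------------------------------------------------
# tabular calibration generator
# ---------------------------------------------------------------------------


def generate_analysis_cohort(
    n: int,
    seed: int,
    true_beta: float = 0.30,
    outcome: str = "global_cognition",
    covariate_effects: Dict[str, float] | None = None,
    dti_noise_sd: float = 0.0,
    wmh_loading: float = -0.7,
    nbv_loading: float = 0.2,
    n_sites: int = 1,
    outcome_driver: str = "signal",
    residual_sd: Optional[float] = None,
) -> pd.DataFrame:
    """Subject-level analysis table with exactly known standardized effects.

    The all-WM FA median is an affine readout of latent integrity (plus
    optional measurement noise ``dti_noise_sd`` on the standardized scale),
    so with the default ``dti_noise_sd=0`` the true standardized coefficient
    of ``fa_median_wm`` on the outcome is exactly ``true_beta``.  WMH lesion
    load and lacune counts are noisy monotone functions of the same latent
    integrity — they influence the outcome only through it (the mediation
    structure).  The outcome has unit variance by construction.

    ``outcome_driver`` selects what the outcome loads on: the measured DTI
    ``signal`` (default; keeps the standardized coefficient exactly
    ``true_beta`` even with measurement noise) or the latent ``integrity``
    itself (the pure mediation structure, where the DTI metric is a proxy).
    """
    if outcome_driver not in ("signal", "integrity"):
        raise ConfigError("outcome_driver must be 'signal' or 'integrity'")
    if covariate_effects is None:
        covariate_effects = dict(DEFAULT_COVARIATE_EFFECTS)
    rng = np.random.default_rng(seed)
    integrity = rng.standard_normal(n)
    z_age = rng.standard_normal(n)
    sex = (rng.uniform(size=n) < 0.59).astype(int)
    z_sex = (sex - 0.59) / np.sqrt(0.59 * 0.41)
    z_iq = rng.standard_normal(n)

    if dti_noise_sd > 0:
        signal = (integrity + dti_noise_sd * rng.standard_normal(n)) / np.sqrt(
            1 + dti_noise_sd**2
        )
    else:
        signal = integrity
    fa_median_wm = 0.335 + 0.028 * signal
    md_peak_height_wm = 0.0133 + 0.0023 * (
        0.8 * signal + 0.6 * rng.standard_normal(n)
    )

    w_lat = wmh_loading * integrity + np.sqrt(1 - wmh_loading**2) * rng.standard_normal(n)
    sigma = np.sqrt(np.log1p((2.2 / 3.4) ** 2))
    mu = np.log(3.4) - 0.5 * sigma**2
    wmh_lesion_load = np.exp(mu + sigma * w_lat)
    lacune_count = rng.poisson(4.4 * np.exp(0.35 * wmh_loading * integrity))

    nbv_lat = nbv_loading * integrity + np.sqrt(1 - nbv_loading**2) * rng.standard_normal(n)
    whole_nbv = 1356.0 + 108.0 * nbv_lat
    gm_nbv = 714.0 + 0.55 * 108.0 * nbv_lat + 30.0 * rng.standard_normal(n)
    wm_nbv = whole_nbv - gm_nbv

    if residual_sd is not None:
        noise = float(residual_sd)
    else:
        explained = true_beta**2 + sum(c**2 for c in covariate_effects.values())
        noise = np.sqrt(max(1.0 - explained, 0.02))
    driver = signal if outcome_driver == "signal" else integrity
    y = (
        true_beta * driver
        + covariate_effects["age"] * z_age
        + covariate_effects["sex"] * z_sex
        + covariate_effects["premorbid_iq"] * z_iq
        + noise * rng.standard_normal(n)
    )
    df = pd.DataFrame(
        {
            "site": (np.arange(n) % n_sites) + 1,
            "age": 68.2 + 9.1 * z_age,
            "sex": sex,
            "premorbid_iq": 115.8 + 8.1 * z_iq,
            "integrity": integrity,
            "fa_median_wm": fa_median_wm,
            "md_peak_height_wm": md_peak_height_wm,
            "wmh_lesion_load": wmh_lesion_load,
            "lacune_count": lacune_count,
            "whole_nbv": whole_nbv,
            "gm_nbv": gm_nbv,
            "wm_nbv": wm_nbv,
            outcome: y,
        }
    )
    df.index = [f"S{i:04d}" for i in range(n)]
    return df
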