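"""End-to-end orchestration: imaging markers -> cognition -> models -> sites.

``run_pipeline`` ties the stages into one reproducible run directory with
publication-shaped CSV tables, an exclusion audit trail, a structured
JSON-lines log and a manifest (seed + config hash).  Re-running with the
same configuration reproduces all outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import cognition as cog
from . import models as mdl
from . import sites as sitemod
from .errors import ConfigError, SampleSizeError, SvdMarkersError
from .histograms import summarize_subject
from .images import SubjectImaging
from .segmentation import hard_segment, make_masks
from .synthetic import (
    CohortBundle,
    GeneratorConfig,
    generate_cohort,
    read_cohort,
    synthetic_normative_table,
    write_cohort,
)
from .volumetrics import summarize_subject_volumes


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    input_dir: Optional[str] = None  # pre-generated cohort; None -> simulate
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    tissue_classes: Tuple[str, ...] = ("nawm", "wm")
    alpha: float = 0.05
    # Open-question toggles
    joint_cleaning: bool = True
    lesion_load_denominator: str = "native"
    median_from: str = "histogram"
    imputation_strategy: str = "cohort_min"
    ci_scale: str = "standardized"
    write_volumes: bool = False  # also dump the simulated NIfTI volumes

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        for tc in self.tissue_classes:
            if tc not in ("nawm", "wm"):
                raise ConfigError(f"tissue_classes entries must be 'nawm' or 'wm', got {tc!r}")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ConfigError(f"input_dir does not exist: {self.input_dir}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen_raw = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen_raw:
            cfg.generator = GeneratorConfig(**gen_raw)
        return cfg


def imaging_metrics_table(
    subjects: Sequence[SubjectImaging],
    joint_cleaning: bool = True,
    lesion_load_denominator: str = "native",
    median_from: str = "histogram",
) -> pd.DataFrame:
    """Per-subject MR variables: histogram markers plus volumetrics."""
    rows = []
    for subject in subjects:
        labels = hard_segment(subject.tpm_gm, subject.tpm_wm, subject.tpm_csf, subject.wmh_mask)
        masks = make_masks(labels)
        hsum = summarize_subject(
            subject.fa, subject.md, masks,
            joint_cleaning=joint_cleaning, median_from=median_from,
        )
        vsum = summarize_subject_volumes(subject, lesion_load_denominator)
        row = {"subject_id": subject.subject_id, "site": subject.site_id}
        row.update(hsum.to_flat_dict())
        row.update(
            {
                "whole_nbv": vsum.whole_nbv_ml,
                "gm_nbv": vsum.gm_nbv_ml,
                "wm_nbv": vsum.wm_nbv_ml,
                "wmh_ml": vsum.wmh_ml,
                "wmh_lesion_load": vsum.wmh_lesion_load_pct,
                "lacune_count": vsum.lacune_count,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def cognition_table(
    cohort: pd.DataFrame,
    norms=None,
    imputation_strategy: str = "cohort_min",
) -> Tuple[pd.DataFrame, cog.ImputationLog]:
    """Raw scores -> z-scores -> imputation -> domain composites."""
    norms = norms or synthetic_normative_table()
    task_z = cog.z_transform_table(cohort, norms)
    reasons = pd.DataFrame(
        {t: cohort.get(f"{t}_missing", pd.Series("", index=cohort.index)) for t in cog.TASKS}
    ).fillna("")
    task_z, log = cog.impute_unable(task_z, reasons, strategy=imputation_strategy)
    domains = cog.domain_scores(task_z, reasons)
    for col in ("moca", "ssqol", "euroqol"):
        if col in cohort.columns:
            domains[col] = cohort[col]
    return domains, log


class _JsonlLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def event(self, stage: str, **payload) -> None:
        with self.path.open("a") as f:
            f.write(json.dumps({"stage": stage, **payload}, default=str) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate -> masks/histograms/volumes -> cognition -> models -> sites."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _JsonlLog(out / "log.jsonl")

    # --- cohort ---------------------------------------------------------
    if config.input_dir is not None:
        subjects, cohort = read_cohort(config.input_dir)
        log.event("load", n=len(subjects), input_dir=str(config.input_dir))
        gen_cfg = None
    else:
        gen_cfg = dataclasses.replace(config.generator, seed=config.seed)
        bundle = generate_cohort(gen_cfg)
        subjects, cohort = bundle.subjects, bundle.cohort
        log.event("simulate", n=len(subjects), config_hash=gen_cfg.content_hash())
        if config.write_volumes:
            write_cohort(bundle, out / "cohort_volumes")
    cohort.to_csv(out / "cohort.csv")

    # --- imaging markers ------------------------------------------------
    try:
        imaging = imaging_metrics_table(
            subjects,
            joint_cleaning=config.joint_cleaning,
            lesion_load_denominator=config.lesion_load_denominator,
            median_from=config.median_from,
        )
    except SvdMarkersError as e:
        log.event("imaging", error=str(e))
        raise
    imaging.to_csv(out / "imaging_metrics.csv")
    log.event("imaging", n=len(imaging))

    # --- cognition ------------------------------------------------------
    domains, imp_log = cognition_table(
        cohort, imputation_strategy=config.imputation_strategy
    )
    domains.to_csv(out / "cognition_scores.csv")
    log.event(
        "cognition",
        imputed_tasks=imp_log.n_tasks,
        imputed_participants=imp_log.n_participants,
        imputed_pct=round(imp_log.pct_participants, 1),
    )

    # --- analysis table + exclusion ledger ------------------------------
    data = imaging.drop(columns=["site"]).join(domains).join(
        cohort[["site", "age", "sex", "premorbid_iq"]]
    )
    if "mri_fail" in cohort.columns:
        data["mri_fail"] = cohort["mri_fail"]
    else:
        data["mri_fail"] = False
    ledger = cog.exclusion_ledger(data, outcome_cols=list(cog.OUTCOMES))
    (out / "exclusion_ledger.json").write_text(
        json.dumps(
            {
                "cohort_n": ledger.cohort_n,
                "n_complete_imaging": ledger.n_complete_imaging,
                "n_per_outcome": ledger.n_per_outcome,
                "audit": ledger.audit,
            },
            indent=2,
            default=str,
        )
    )
    excluded = {a["subject"] for a in ledger.audit if a["stage"] in ("site_n1", "mri_failure", "missing_covariate")}
    analysis = data.drop(index=[i for i in excluded if i in data.index])
    # site stratification cannot carry sites reduced below two subjects
    counts = analysis["site"].value_counts()
    small_sites = counts.index[counts < 2]
    for s in small_sites:
        log.event("ledger", dropped_site=int(s), reason="fewer than 2 analysable subjects")
    analysis = analysis[~analysis["site"].isin(small_sites)]
    log.event("ledger", n_analysis=len(analysis), n_imaging=ledger.n_complete_imaging)

    # --- impairment profile ---------------------------------------------
    imp = cog.impairment_tests(analysis)
    pd.DataFrame([dataclasses.asdict(t) for t in imp]).to_csv(
        out / "impairment_tests.csv", index=False
    )

    # --- association models ---------------------------------------------
    outcomes = list(cog.OUTCOMES)
    complex_rows = []
    selections_all: Dict[str, Dict[str, mdl.SelectionResult]] = {}
    for tc in config.tissue_classes:
        screen = mdl.simple_models(analysis, outcomes, tissue_class=tc)
        screen.to_csv(out / f"simple_models_{tc}.csv", index=False)
        selections = {o: mdl.select_variables(screen, o, tc) for o in outcomes}
        selections_all[tc] = selections
        results = mdl.complex_models(analysis, selections, outcomes)
        table = mdl.complex_results_table(results)
        table.insert(0, "tissue_class", tc)
        if config.ci_scale == "unstandardized":
            raw = {
                (o, t.term): t
                for o, r in results.items()
                for t in r.terms.values()
            }
            table["ci_lo"] = [raw[(o, t)].ci_lo_raw for o, t in zip(table["outcome"], table["term"])]
            table["ci_hi"] = [raw[(o, t)].ci_hi_raw for o, t in zip(table["outcome"], table["term"])]
        complex_rows.append(table)
        for o, r in results.items():
            if r.high_vif_terms:
                log.event("models", outcome=o, tissue_class=tc, high_vif=r.high_vif_terms)
    complex_table = pd.concat(complex_rows, ignore_index=True)
    complex_table.to_csv(out / "complex_models.csv", index=False)
    log.event("models", n_complex=int(len(complex_table[["tissue_class", "outcome"]].drop_duplicates())))

    # --- site heterogeneity ---------------------------------------------
    site_tests = {}
    for metric in ("fa_median_wm", "md_peak_height_wm"):
        a_p, k_p = sitemod.between_site_tests(analysis[metric], analysis["site"])
        site_tests[metric] = {"anova_p": a_p, "kruskal_p": k_p}
    (out / "site_tests.json").write_text(json.dumps(site_tests, indent=2))

    class_rows: List[dict] = []
    tc = config.tissue_classes[-1]
    pooled = mdl.complex_models(
        analysis, selections_all[tc], ["global_cognition"]
    )["global_cognition"]
    sel = selections_all[tc]["global_cognition"]
    est = pooled.term(sel.dti_variable)
    slopes = {}
    for s in sorted(analysis["site"].unique()):
        try:
            r = sitemod.per_site_complex(analysis, s, sel)
            slopes[s] = r.term(sel.dti_variable).beta
        except SampleSizeError as e:
            log.event("sites", site=int(s), skipped=str(e))
    for c in sitemod.classify_site_fits(slopes, est.beta, (est.ci_lo, est.ci_hi)):
        class_rows.append(dataclasses.asdict(c))
    pd.DataFrame(class_rows).to_csv(out / "site_classification.csv", index=False)

    # --- manifest --------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "run_config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("generator", "out_dir")
        },
        "generator_hash": gen_cfg.content_hash() if gen_cfg is not None else None,
        "n_subjects": len(subjects),
        "n_analysis": int(len(analysis)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.event("done", out_dir=str(out))
    return out
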