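"""Cognitive z-scores, domain composites, missing-data rules and the analysis ledger.

Seven tasks feed four domains:

* Processing speed — digit symbol coding (DSC), Trail Making Test part A
* Mental flexibility — Trail Making Test part B
* Verbal fluency — phonemic ('FAS') and semantic (animals) fluency
* Verbal memory — RAVLT immediate and delayed recall

Raw scores are z-transformed against age-scaled norms, with timed tasks
(TMT) sign-flipped so that higher z always means better performance.  Two
missingness mechanisms are handled: a subject *unable* to complete a task
receives the lowest available z-score for that task (cohort-wide minimum),
while data missing for *other* reasons simply drop that task from its domain
composite.  Domain scores are the mean of available member tasks, and Global
cognition the mean of the four domains.  MoCA, SSQoL and EuroQoL are analysed
as raw scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, NormLookupError

TASKS = ("dsc", "tmt_a", "tmt_b", "fas", "animals", "ravlt_imm", "ravlt_del")
DOMAIN_TASKS: Dict[str, Tuple[str, ...]] = {
    "processing_speed": ("dsc", "tmt_a"),
    "mental_flexibility": ("tmt_b",),
    "verbal_fluency": ("fas", "animals"),
    "verbal_memory": ("ravlt_imm", "ravlt_del"),
}
DOMAINS = tuple(DOMAIN_TASKS)
#: Outcomes entering the regression layer: domain composites analysed as
#: z-composites; MoCA/SSQoL/EuroQoL analysed as raw scores.
OUTCOMES = ("global_cognition",) + DOMAINS + ("moca", "ssqol", "euroqol")

UNABLE = "unable"
OTHER = "other"


class NormativeTable:
    """Age-banded normative means/SDs per task, with score orientation.

    Stored as a DataFrame with columns ``task, age_lo, age_hi, mean, sd,
    orientation`` where orientation is ``higher_better`` or ``higher_worse``
    (timed tasks).  Age bands are matched as ``age_lo <= age < age_hi`` with
    the top band closed.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"task", "age_lo", "age_hi", "mean", "sd", "orientation"}
        missing = required - set(table.columns)
        if missing:
            raise NormLookupError(f"normative table missing columns {sorted(missing)}")
        if (table["sd"] <= 0).any():
            raise NormLookupError("normative sd values must be positive")
        self.table = table.reset_index(drop=True)

    def lookup(self, task: str, age: float) -> Tuple[float, float, str]:
        rows = self.table[self.table["task"] == task]
        if rows.empty:
            raise NormLookupError(f"no normative rows for task {task!r}")
        top = rows["age_hi"].max()
        for _, r in rows.iterrows():
            if r["age_lo"] <= age < r["age_hi"] or (age == top == r["age_hi"]):
                return float(r["mean"]), float(r["sd"]), str(r["orientation"])
        raise NormLookupError(f"age {age} outside normative support for task {task!r}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "NormativeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def z_transform(raw_score: float, task: str, age: float, norms: NormativeTable) -> float:
    """Standardize one raw score; timed tasks are flipped to higher-is-better."""
    mean, sd, orientation = norms.lookup(task, age)
    z = (raw_score - mean) / sd
    if orientation == "higher_worse":
        z = -z
    return float(z)


def z_transform_table(
    raw: pd.DataFrame, norms: NormativeTable, age_col: str = "age"
) -> pd.DataFrame:
    """Z-transform all task columns of a cohort table; NaN raw scores stay NaN."""
    out = pd.DataFrame(index=raw.index)
    for task in TASKS:
        zs = []
        for _, row in raw.iterrows():
            v = row[task]
            zs.append(np.nan if pd.isna(v) else z_transform(v, task, row[age_col], norms))
        out[task] = zs
    return out


@dataclass
class ImputationLog:
    entries: List[Tuple[object, str]] = field(default_factory=list)
    n_tasks: int = 0
    n_participants: int = 0
    cohort_size: int = 0

    @property
    def pct_participants(self) -> float:
        if self.cohort_size == 0:
            return 0.0
        return 100.0 * self.n_participants / self.cohort_size


def impute_unable(
    task_z: pd.DataFrame, reasons: pd.DataFrame, strategy: str = "cohort_min"
) -> Tuple[pd.DataFrame, ImputationLog]:
    """Replace 'unable' entries with the lowest available z-score for that task.

    With ``strategy='cohort_min'`` (default) the floor is the cohort-wide
    minimum of the task's observed values; with ``'subject_min'`` it is the
    subject's own lowest observed z across the other tasks.  Entries missing
    for other reasons remain missing.  Returns the completed table and a log
    of affected (subject, task) pairs.
    """
    if strategy not in ("cohort_min", "subject_min"):
        raise DegenerateDataError("strategy must be 'cohort_min' or 'subject_min'")
    out = task_z.copy()
    log = ImputationLog(cohort_size=len(task_z))
    affected_subjects = set()
    for task in TASKS:
        unable_idx = reasons.index[reasons[task] == UNABLE]
        if len(unable_idx) == 0:
            continue
        observed = task_z[task].dropna()
        if observed.empty:
            raise DegenerateDataError(
                f"task {task!r} has 'unable' entries but no observed values to impute from"
            )
        floor = float(observed.min())
        for idx in unable_idx:
            if strategy == "subject_min":
                own = task_z.loc[idx].dropna()
                if own.empty:
                    raise DegenerateDataError(
                        f"subject {idx!r} has no observed z-scores to impute from"
                    )
                out.loc[idx, task] = float(own.min())
            else:
                out.loc[idx, task] = floor
            log.entries.append((idx, task))
            affected_subjects.add(idx)
    log.n_tasks = len(log.entries)
    log.n_participants = len(affected_subjects)
    return out, log


def domain_scores(task_z: pd.DataFrame, reasons: pd.DataFrame | None = None) -> pd.DataFrame:
    """Domain composites and Global cognition from a completed z-table.

    Entries missing for 'other' reasons are NaN and simply drop out of their
    domain mean; a domain with no available member is missing, and Global
    cognition is missing whenever any domain is.
    """
    out = pd.DataFrame(index=task_z.index)
    for domain, members in DOMAIN_TASKS.items():
        out[domain] = task_z[list(members)].mean(axis=1, skipna=True)
    out["global_cognition"] = out[list(DOMAINS)].mean(axis=1, skipna=False)
    return out


@dataclass
class ImpairmentTest:
    domain: str
    n: int
    mean: float
    sem: float
    t: float
    p: float


def impairment_tests(domain_table: pd.DataFrame) -> List[ImpairmentTest]:
    """Two-sided one-sample t-tests of each domain (and Global) against zero."""
    results = []
    for domain in list(DOMAINS) + ["global_cognition"]:
        vals = domain_table[domain].dropna().to_numpy()
        if vals.size < 3:
            raise DegenerateDataError(f"domain {domain!r} has n={vals.size} < 3")
        if np.std(vals, ddof=1) == 0:
            raise DegenerateDataError(f"domain {domain!r} has zero variance")
        t, p = stats.ttest_1samp(vals, 0.0)
        results.append(
            ImpairmentTest(
                domain=domain,
                n=int(vals.size),
                mean=float(vals.mean()),
                sem=float(stats.sem(vals)),
                t=float(t),
                p=float(p),
            )
        )
    return results


@dataclass
class ExclusionLedger:
    """Per-outcome analysis n plus the full audit trail of exclusions."""

    cohort_n: int
    n_complete_imaging: int
    n_per_outcome: Dict[str, int]
    audit: List[Dict[str, object]]


def exclusion_ledger(
    cohort: pd.DataFrame,
    outcome_cols: Sequence[str],
    site_col: str = "site",
    mri_fail_col: str = "mri_fail",
    covariate_col: str = "premorbid_iq",
) -> ExclusionLedger:
    """Apply the study's exclusion cascade and report per-outcome analysis n.

    Order of operations: (1) drop any site recruiting a single subject, since
    a one-subject stratum cannot support site stratification; (2) drop
    subjects whose MRI acquisition failed; (3) drop subjects missing the
    model covariate (premorbid IQ) from every model; (4) drop subjects
    missing an outcome from that outcome's models only.  Missingness is NaN
    in the respective column.
    """
    audit: List[Dict[str, object]] = []
    df = cohort

    site_counts = df[site_col].value_counts()
    lonely_sites = site_counts.index[site_counts == 1]
    for s in lonely_sites:
        for idx in df.index[df[site_col] == s]:
            audit.append({"subject": idx, "stage": "site_n1", "detail": f"site {s} has n=1"})
    df = df[~df[site_col].isin(lonely_sites)]

    if mri_fail_col in df.columns:
        failed = df.index[df[mri_fail_col].astype(bool)]
        for idx in failed:
            audit.append({"subject": idx, "stage": "mri_failure", "detail": "MRI acquisition problem"})
        df = df.drop(index=failed)
    n_imaging = len(df)

    missing_cov = df.index[df[covariate_col].isna()]
    for idx in missing_cov:
        audit.append(
            {"subject": idx, "stage": "missing_covariate", "detail": f"missing {covariate_col}"}
        )
    base = df.drop(index=missing_cov)

    n_per_outcome: Dict[str, int] = {}
    for col in outcome_cols:
        missing = base.index[base[col].isna()]
        for idx in missing:
            audit.append({"subject": idx, "stage": "missing_outcome", "detail": col})
        n_per_outcome[col] = len(base) - len(missing)

    return ExclusionLedger(
        cohort_n=len(cohort),
        n_complete_imaging=n_imaging,
        n_per_outcome=n_per_outcome,
        audit=audit,
    )
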