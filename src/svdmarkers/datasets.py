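"""Small built-in example tables for the worked examples and desk checks.

``example_simple_screen`` is a published-style Simple-model screen (standardized
betas and p-values for seven MR variables against eight outcomes) from a
multicentre SVD cohort of about one hundred patients; it exercises the
variable-selection rule without refitting anything.  The enrolment/missingness
builders reconstruct the same study's exclusion arithmetic — six sites with
one single-subject site, six MRI acquisition failures, and the handful of
missing cognitive/covariate entries — as a synthetic cohort table.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: Per-site recruitment of the example multicentre cohort.
EXAMPLE_SITE_SIZES = {1: 48, 2: 29, 3: 14, 4: 11, 5: 6, 6: 1}
#: MRI acquisition failures per site in the example cohort.
EXAMPLE_MRI_FAILURES = {1: 2, 4: 4}


def example_simple_screen() -> pd.DataFrame:
    """Load the built-in example Simple-model screen (tidy table)."""
    with resources.files("svdmarkers.data").joinpath("example_simple_screen.csv").open() as f:
        return pd.read_csv(f, keep_default_na=False, na_values=[])


def example_enrolment_table() -> pd.DataFrame:
    """Cohort table reproducing the example study's exclusion cascade.

    109 subjects across six sites; `mri_fail` flags the six acquisition
    failures; among the 102 subjects with complete imaging, one is missing
    Verbal fluency, one is missing Verbal memory plus premorbid IQ, and one
    is missing premorbid IQ only.  All values are placeholders (zeros) —
    only the missingness pattern matters.
    """
    rows = []
    sid = 0
    for site, n in EXAMPLE_SITE_SIZES.items():
        fails = EXAMPLE_MRI_FAILURES.get(site, 0)
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"S{sid:03d}",
                    "site": site,
                    "mri_fail": i < fails,
                    "premorbid_iq": 0.0,
                    "global_cognition": 0.0,
                    "processing_speed": 0.0,
                    "mental_flexibility": 0.0,
                    "verbal_fluency": 0.0,
                    "verbal_memory": 0.0,
                    "moca": 0.0,
                    "ssqol": 0.0,
                    "euroqol": 0.0,
                }
            )
            sid += 1
    df = pd.DataFrame(rows).set_index("subject_id")
    eligible = df.index[(~df["mri_fail"]) & (df["site"] != 6)]
    df.loc[eligible[0], "verbal_fluency"] = np.nan
    df.loc[eligible[1], ["verbal_memory", "premorbid_iq"]] = np.nan
    df.loc[eligible[2], "premorbid_iq"] = np.nan
    return df


def example_unable_pattern(n_cohort: int = 109, n_participants: int = 13, n_tasks: int = 15):
    """(task-z table, reasons table) with the example study's 'unable' pattern.

    ``n_tasks`` 'unable' entries spread over ``n_participants`` subjects: the
    first ``n_tasks - n_participants`` affected subjects carry two unable
    tasks each, the rest one.  Observed z-scores are a fixed spread so the
    per-task minimum is well defined.
    """
    from .cognition import TASKS, UNABLE

    if not n_participants <= n_tasks <= 2 * n_participants:
        raise ValueError("pattern requires n_participants <= n_tasks <= 2*n_participants")
    rng = np.random.default_rng(0)
    z = pd.DataFrame(
        rng.normal(-0.5, 1.0, size=(n_cohort, len(TASKS))),
        columns=list(TASKS),
        index=[f"S{i:03d}" for i in range(n_cohort)],
    )
    reasons = pd.DataFrame("", columns=list(TASKS), index=z.index)
    n_double = n_tasks - n_participants
    for k in range(n_participants):
        subj = z.index[k]
        tasks = [TASKS[k % len(TASKS)]]
        if k < n_double:
            tasks.append(TASKS[(k + 1) % len(TASKS)])
        for t in tasks:
            reasons.loc[subj, t] = UNABLE
            z.loc[subj, t] = np.nan
    return z, reasons
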