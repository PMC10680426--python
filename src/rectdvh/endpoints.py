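"""Binary late-toxicity endpoints from longitudinal graded records.

Five gastrointestinal symptoms are graded on a unified 0–2+ scale
(grade 1 = event without intervention, grade 2 = event requiring
intervention) at a baseline visit (month 0) and seven late follow-ups
(months 6, 12, 18, 24, 36, 48, 60).  Eight binary endpoints are derived:
G1+ and G2+ for stool frequency, rectal bleeding and proctitis, plus
G1+ for sphincter control and for stricture/ulcer.

Derivation rules, applied independently per patient-endpoint:

* nonzero baseline grade → excluded for that endpoint;
* otherwise any late visit at or above the grade threshold → case
  (a single event suffices, regardless of attendance);
* otherwise a control only if at least 4 of the 7 late visits were
  completed; fewer → excluded for insufficient follow-up.

A completed visit is any visit with a recorded grade, including 0 —
completeness is about attendance, not symptoms.  A missing baseline row is
treated as baseline grade 0 (counted and logged).  Grades above 2 count as
>= 2 for both thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

log = logging.getLogger(__name__)

__all__ = [
    "SYMPTOMS",
    "ENDPOINT_LABELS",
    "LATE_VISIT_MONTHS",
    "VISIT_MONTHS",
    "EndpointStatus",
    "derive_endpoint",
    "build_outcome_table",
]

SYMPTOMS: tuple[str, ...] = (
    "frequency",
    "bleeding",
    "proctitis",
    "sphincter_control",
    "stricture_ulcer",
)

#: The 8 endpoint labels as (label, symptom, grade threshold).
ENDPOINT_LABELS: tuple[tuple[str, str, int], ...] = (
    ("frequency_g1plus", "frequency", 1),
    ("frequency_g2plus", "frequency", 2),
    ("bleeding_g1plus", "bleeding", 1),
    ("bleeding_g2plus", "bleeding", 2),
    ("proctitis_g1plus", "proctitis", 1),
    ("proctitis_g2plus", "proctitis", 2),
    ("sphincter_control_g1plus", "sphincter_control", 1),
    ("stricture_ulcer_g1plus", "stricture_ulcer", 1),
)

LATE_VISIT_MONTHS: tuple[int, ...] = (6, 12, 18, 24, 36, 48, 60)
VISIT_MONTHS: tuple[int, ...] = (0,) + LATE_VISIT_MONTHS

MIN_COMPLETED_LATE_VISITS = 4

STATUS_CASE = "case"
STATUS_CONTROL = "control"
STATUS_EXCL_BASELINE = "excluded_baseline"
STATUS_EXCL_FOLLOWUP = "excluded_insufficient_followup"


@dataclass
class EndpointStatus:
    patient_id: str
    endpoint_label: str
    status: str


def _check_records(records: pd.DataFrame) -> None:
    required = {"patient_id", "endpoint_name", "visit_month", "grade"}
    missing = required - set(records.columns)
    if missing:
        raise DataError(f"toxicity records missing columns: {sorted(missing)}")
    bad_months = set(records["visit_month"].unique()) - set(VISIT_MONTHS)
    if bad_months:
        raise DataError(f"visit months outside the fixed schedule: {sorted(bad_months)}")
    dup = records.duplicated(subset=["patient_id", "endpoint_name", "visit_month"])
    if dup.any():
        rows = records.loc[dup, ["patient_id", "endpoint_name", "visit_month"]].iloc[0]
        raise DataError(f"duplicate visit rows, e.g. {tuple(rows)}")


def derive_endpoint(records: pd.DataFrame, grade_threshold: int) -> str:
    """Status for one patient-endpoint from its visit rows.

    ``records`` holds the rows of a single (patient, symptom); rows with a
    missing (NaN) grade are non-completed visits.
    """
    _check_records(records)
    if records[["patient_id", "endpoint_name"]].drop_duplicates().shape[0] > 1:
        raise DataError("derive_endpoint expects rows of a single patient-endpoint")

    grade = records.set_index("visit_month")["grade"]
    baseline = grade.get(0, np.nan)
    if pd.isna(baseline):
        log.debug("missing baseline treated as grade 0")
        baseline = 0
    if baseline >= 1:
        return STATUS_EXCL_BASELINE

    late = grade.reindex(LATE_VISIT_MONTHS)
    completed = late.notna()
    if (late[completed] >= grade_threshold).any():
        return STATUS_CASE
    if int(completed.sum()) >= MIN_COMPLETED_LATE_VISITS:
        return STATUS_CONTROL
    return STATUS_EXCL_FOLLOWUP


def build_outcome_table(records: pd.DataFrame) -> pd.DataFrame:
    """Case/control/exclusion status matrix: patients × the 8 endpoint labels.

    Statuses are computed independently per endpoint, so the analysable n
    differs between endpoints.  Vectorised over the cohort.
    """
    if records.empty:
        return pd.DataFrame(columns=[lab for lab, _, _ in ENDPOINT_LABELS])
    _check_records(records)

    is_baseline = records["visit_month"] == 0
    base = (
        records[is_baseline]
        .set_index(["patient_id", "endpoint_name"])["grade"]
        .fillna(0.0)
    )
    late_rows = records[~is_baseline]
    grp = late_rows.groupby(["patient_id", "endpoint_name"])["grade"]
    max_late = grp.max()          # NaN-ignoring; NaN if nothing completed
    n_completed = grp.count()

    patients = records["patient_id"].unique()
    idx = pd.MultiIndex.from_product(
        [patients, SYMPTOMS], names=["patient_id", "endpoint_name"]
    )
    base = base.reindex(idx, fill_value=0.0)
    n_missing_baseline = int(base.isna().sum())
    if n_missing_baseline:
        log.info("build_outcome_table: %d missing baselines treated as grade 0", n_missing_baseline)
        base = base.fillna(0.0)
    max_late = max_late.reindex(idx)
    n_completed = n_completed.reindex(idx, fill_value=0)

    out = pd.DataFrame(index=pd.Index(patients, name="patient_id"))
    for label, symptom, threshold in ENDPOINT_LABELS:
        b = base.xs(symptom, level="endpoint_name").reindex(patients)
        m = max_late.xs(symptom, level="endpoint_name").reindex(patients)
        c = n_completed.xs(symptom, level="endpoint_name").reindex(patients)
        status = np.where(
            b >= 1,
            STATUS_EXCL_BASELINE,
            np.where(
                m.fillna(-1) >= threshold,
                STATUS_CASE,
                np.where(c >= MIN_COMPLETED_LATE_VISITS, STATUS_CONTROL, STATUS_EXCL_FOLLOWUP),
            ),
        )
        out[label] = status

    for label in out.columns:
        counts = out[label].value_counts().to_dict()
        log.info("endpoint %s: %s", label, counts)
    return out
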