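"""Cohort construction: valid-ACT selection, index dating, inclusion/exclusion.

A patient's index date is the date of their first *valid* ACT.  A valid ACT
(1) has complete responses to all five items, (2) does not share its date
with another ACT for the same patient, and (3) does not fall within 28 days
*after* another ACT for the same patient.  The 28-day rule exists because
the ACT has a 4-week recall period: two measurements inside one recall
window cannot be disambiguated.  The rule is applied backward-looking only,
so a later repeat can never retroactively invalidate an otherwise-first
valid ACT.

Inclusion/exclusion, applied in order (each stage logged in the attrition
report):

1. >= 1 asthma diagnosis (ICD-9 493.xx / ICD-10 J45.xx / SNOMED H33xx) on
   or before index;
2. a valid index ACT inside the study window (2015-01-01 .. 2018-12-31);
3. >= 1 prescription of an asthma-treatment class dated in the exposure
   window [index - 210 d, index - 29 d] (the 182 days preceding the 4-week
   recall period, both ends closed);
4. database activity (an encounter for any reason) at least 182 days before
   index;
5. no COPD diagnosis on or before index;
6. a non-missing calendar year of birth.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .data_model import ASTHMA_TREATMENT_CLASSES, ActRecord, EmrDataset

__all__ = [
    "IndexedPatient",
    "AttritionReport",
    "is_valid_act",
    "select_index",
    "build_cohort",
    "STUDY_START",
    "STUDY_END",
    "EXPOSURE_LOOKBACK_DAYS",
    "RECALL_DAYS",
    "ACTIVITY_DAYS",
]

STUDY_START = datetime.date(2015, 1, 1)
STUDY_END = datetime.date(2018, 12, 31)
#: recall period of the ACT questionnaire (days)
RECALL_DAYS = 28
#: "6 months" of treatment lookback, fixed at 182 days
ACTIVITY_DAYS = 182
#: exposure window spans [index - 210, index - 29]
EXPOSURE_LOOKBACK_DAYS = RECALL_DAYS + ACTIVITY_DAYS  # 210

ASTHMA_CODE_STEMS = {"ICD9": ("493",), "ICD10": ("J45",), "SNOMED": ("H33",)}
#: COPD stems are configurable; defaults cover chronic bronchitis, emphysema,
#: bronchiectasis and unspecified chronic airway obstruction.
DEFAULT_COPD_CODE_STEMS = {
    "ICD9": ("490", "491", "492", "494", "496"),
    "ICD10": ("J40", "J41", "J42", "J43", "J44", "J47"),
    "SNOMED": (),
}


@dataclass(frozen=True)
class IndexedPatient:
    patient_id: str
    index_date: datetime.date
    index_act: ActRecord
    exposure_window: tuple  # (start_date, end_date), both closed

    @property
    def window_start(self) -> datetime.date:
        return self.exposure_window[0]

    @property
    def window_end(self) -> datetime.date:
        return self.exposure_window[1]


@dataclass
class AttritionReport:
    """Stage-by-stage record counts through inclusion/exclusion."""

    stages: list = field(default_factory=list)  # (label, n_before, n_excluded, n_after)
    #: patient_id -> label of the stage that excluded it
    excluded_at: dict = field(default_factory=dict)

    def add(self, label: str, n_before: int, n_excluded: int) -> None:
        self.stages.append((label, n_before, n_excluded, n_before - n_excluded))

    @property
    def final_n(self) -> int:
        return self.stages[-1][3] if self.stages else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["label", "n_before", "n_excluded", "n_after"]
        ).rename_axis("stage").reset_index()


def is_valid_act(act: ActRecord, all_acts_for_patient) -> bool:
    """True iff *act* is complete, not same-day duplicated, and not a
    within-28-day repeat of an earlier ACT.

    Any ACT record (complete or not) counts as "another measurement" for the
    duplicate and 28-day rules, since an incomplete record still marks an
    administration inside the recall window.
    """
    if any(v is None for v in act.items):
        return False
    for other in all_acts_for_patient:
        if other is act:
            continue
        delta = (act.date - other.date).days
        if delta == 0:
            return False  # same-day duplicate invalidates both
        if 1 <= delta <= RECALL_DAYS:
            return False  # repeat inside the recall period of an earlier ACT
    return True


def select_index(patient_acts) -> Optional[IndexedPatient]:
    """Return the chronologically first valid ACT as the index, or None."""
    valid = [a for a in patient_acts if is_valid_act(a, patient_acts)]
    if not valid:
        return None
    first = min(valid, key=lambda a: a.date)
    start = first.date - datetime.timedelta(days=EXPOSURE_LOOKBACK_DAYS)
    end = first.date - datetime.timedelta(days=RECALL_DAYS + 1)
    return IndexedPatient(
        patient_id=first.patient_id,
        index_date=first.date,
        index_act=first,
        exposure_window=(start, end),
    )


def _matches(code_system: str, code: str, stems) -> bool:
    return any(code.upper().startswith(stem) for stem in stems.get(code_system, ()))


def _by_patient(records):
    out: dict = {}
    for rec in records:
        out.setdefault(rec.patient_id, []).append(rec)
    return out


def build_cohort(
    dataset: EmrDataset,
    study_start: datetime.date = STUDY_START,
    study_end: datetime.date = STUDY_END,
    copd_code_stems=None,
):
    """Apply inclusion/exclusion criteria; return (indexed patients, attrition).

    An empty cohort is a legal result.  The attrition counts depend on the
    stage order documented in the module docstring; re-running on the same
    dataset reproduces the identical report.
    """
    copd_stems = DEFAULT_COPD_CODE_STEMS if copd_code_stems is None else copd_code_stems
    acts = _by_patient(dataset.act_records)
    dxs = _by_patient(dataset.diagnoses)
    rxs = _by_patient(dataset.prescriptions)
    encs = _by_patient(dataset.encounters)

    alive = [p.patient_id for p in dataset.patients]
    patients = {p.patient_id: p for p in dataset.patients}
    index = {pid: select_index(acts.get(pid, [])) for pid in alive}
    report = AttritionReport()

    def stage(label, keep):
        nonlocal alive
        n_before = len(alive)
        kept = []
        for pid in alive:
            if keep(pid):
                kept.append(pid)
            else:
                report.excluded_at[pid] = label
        alive = kept
        report.add(label, n_before, n_before - len(alive))

    def has_asthma_dx(pid):
        # anchored on index when one exists; patients with no valid ACT are
        # screened on ever-recorded codes (they fall out at the next stage)
        limit = index[pid].index_date if index[pid] else None
        return any(
            _matches(d.code_system, d.code, ASTHMA_CODE_STEMS)
            and (limit is None or d.date <= limit)
            for d in dxs.get(pid, [])
        )

    def has_valid_index(pid):
        ip = index[pid]
        return ip is not None and study_start <= ip.index_date <= study_end

    def treated(pid):
        ip = index[pid]
        return any(
            r.drug_class in ASTHMA_TREATMENT_CLASSES
            and ip.window_start <= r.date <= ip.window_end
            for r in rxs.get(pid, [])
        )

    def active(pid):
        cutoff = index[pid].index_date - datetime.timedelta(days=ACTIVITY_DAYS)
        return any(e.date <= cutoff for e in encs.get(pid, []))

    def no_copd(pid):
        limit = index[pid].index_date
        return not any(
            _matches(d.code_system, d.code, copd_stems) and d.date <= limit
            for d in dxs.get(pid, [])
        )

    def has_birth_year(pid):
        return patients[pid].birth_year is not None

    stage("asthma_diagnosis", has_asthma_dx)
    stage("valid_index_act", has_valid_index)
    stage("treated_in_exposure_window", treated)
    stage("activity_182d_before_index", active)
    stage("no_copd_diagnosis", no_copd)
    stage("birth_year_present", has_birth_year)

    cohort = [index[pid] for pid in alive]
    return cohort, report
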