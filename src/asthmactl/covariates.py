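"""Derivation of the confounder adjustment set for each indexed patient.

Covariates are derived relative to the index date: age as index calendar
year minus birth year; race collapsed to white / african_american / other /
unknown (unknown when entries conflict or are absent); ethnicity to
hispanic / non_hispanic / missing; smoking with the precedence
current-at-closest-record > ever-former > consistently-non-smoker > unknown;
BMI from the on-index or nearest prior observation with WHO category cuts
(18.5 / 25 / 30, left-closed); visit type from the specialty of the
index-day encounter.
"""

from __future__ import annotations

import datetime
from typing import Optional

import pandas as pd

__all__ = [
    "derive_age",
    "derive_race",
    "derive_ethnicity",
    "derive_smoking",
    "derive_bmi",
    "derive_visit_type",
    "derive_covariates",
    "RACE_LEVELS",
    "ETHNICITY_LEVELS",
    "SMOKING_LEVELS",
    "BMI_LEVELS",
    "VISIT_LEVELS",
]

RACE_LEVELS = ("white", "african_american", "other", "unknown")
ETHNICITY_LEVELS = ("non_hispanic", "hispanic", "missing")
SMOKING_LEVELS = ("non_smoker", "former", "current", "unknown")
BMI_LEVELS = ("normal", "underweight", "overweight", "obese", "unknown")
VISIT_LEVELS = ("primary_care", "specialist", "other", "unknown")

_PRIMARY_CARE = {"internal medicine", "general medicine", "family medicine"}
_SPECIALIST = {"allergy and immunology", "pulmonary disease", "emergency medicine"}

_RACE_MAP = {
    "white": "white",
    "black/african american": "african_american",
    "black": "african_american",
    "african american": "african_american",
}


def derive_age(birth_year: int, index_date: datetime.date) -> int:
    """Index calendar year minus birth year."""
    age = index_date.year - birth_year
    if age < 0:
        raise ValueError(f"negative age from birth_year={birth_year}, index={index_date}")
    return age


def derive_race(entries) -> str:
    """Single consistent raw value mapped to the 4-level coding; conflicts
    or absent documentation give unknown."""
    raw = {v for _, v in entries}
    if len(raw) != 1:
        return "unknown"
    return _RACE_MAP.get(raw.pop().lower(), "other")


def derive_ethnicity(entries) -> str:
    raw = {v for _, v in entries}
    if len(raw) != 1:
        return "missing"
    return "hispanic" if raw.pop() == "hispanic" else "non_hispanic"


def _on_or_before(records, index_date):
    return [r for r in records if r.date <= index_date]


def _closest(records, index_date):
    # ties on the same day resolve to the last-written record (stable order)
    return min(reversed(records), key=lambda r: (index_date - r.date).days)


def derive_smoking(records, index_date: datetime.date) -> str:
    """Smoking status at index from dated smoking_status observations.

    The three printed definitions overlap; precedence is: current status on
    the record closest to index, then former at any time on or before index,
    then non-smoker when every record says so.  Records after index are
    ignored.
    """
    recs = _on_or_before([r for r in records if r.kind == "smoking_status"], index_date)
    if not recs:
        return "unknown"
    if _closest(recs, index_date).value == "current smoker":
        return "current"
    if any(r.value == "former smoker" for r in recs):
        return "former"
    if all(r.value == "non-smoker" for r in recs):
        return "non_smoker"
    return "unknown"


def bmi_category(value: float) -> str:
    if value < 18.5:
        return "underweight"
    if value < 25:
        return "normal"
    if value < 30:
        return "overweight"
    return "obese"


def derive_bmi(records, index_date: datetime.date):
    """(value, category) from the on-index or nearest prior BMI observation."""
    recs = _on_or_before([r for r in records if r.kind == "bmi"], index_date)
    if not recs:
        return None, "unknown"
    value = float(_closest(recs, index_date).value)
    return value, bmi_category(value)


def derive_visit_type(encounters, index_date: datetime.date) -> str:
    """Visit type of the index-day encounter, via the printed specialty lists.

    Multiple same-day encounters resolve specialist > primary_care > other;
    no index-day encounter, or none with a recorded specialty, gives unknown.
    """
    kinds = set()
    for e in encounters:
        if e.date != index_date or e.provider_specialty is None:
            continue
        s = e.provider_specialty.lower()
        if s in _SPECIALIST:
            kinds.add("specialist")
        elif s in _PRIMARY_CARE:
            kinds.add("primary_care")
        else:
            kinds.add("other")
    for k in ("specialist", "primary_care", "other"):
        if k in kinds:
            return k
    return "unknown"


def derive_covariates(indexed_patients, dataset) -> pd.DataFrame:
    """One covariate row per indexed patient, keyed by patient_id."""
    patients = {p.patient_id: p for p in dataset.patients}
    obs: dict = {}
    for o in dataset.observations:
        obs.setdefault(o.patient_id, []).append(o)
    encs: dict = {}
    for e in dataset.encounters:
        encs.setdefault(e.patient_id, []).append(e)

    rows = []
    for ip in indexed_patients:
        p = patients[ip.patient_id]
        bmi_value, bmi_cat = derive_bmi(obs.get(ip.patient_id, []), ip.index_date)
        rows.append(
            {
                "patient_id": ip.patient_id,
                "age_years": derive_age(p.birth_year, ip.index_date),
                "sex": p.sex,
                "race": derive_race(p.race_entries),
                "ethnicity": derive_ethnicity(p.ethnicity_entries),
                "smoking": derive_smoking(obs.get(ip.patient_id, []), ip.index_date),
                "bmi_value": bmi_value,
                "bmi_category": bmi_cat,
                "visit_type": derive_visit_type(encs.get(ip.patient_id, []), ip.index_date),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "age_years",
            "sex",
            "race",
            "ethnicity",
            "smoking",
            "bmi_value",
            "bmi_category",
            "visit_type",
        ],
    )
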