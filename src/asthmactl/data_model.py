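"""Typed in-memory model of a six-table EMR extract and its CSV exchange dialect.

The analysis consumes flat EMR-style tables: patients, encounters, diagnoses,
prescriptions, ACT questionnaire responses, and clinical observations
(smoking status, BMI).  Each table is held as a list of frozen dataclass
records; :class:`EmrDataset` bundles the six tables.

The on-disk format is UTF-8 comma-separated CSV, ISO-8601 calendar dates,
empty string for a missing cell.  ``read_dataset(write_dataset(d)) == d``
field-for-field for any dataset in canonical (sorted) order.  Readers never
silently coerce: a cell that is neither empty nor parseable raises
:class:`DatasetFormatError` with the offending table and row index.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "PatientRecord",
    "EncounterRecord",
    "DiagnosisRecord",
    "PrescriptionRecord",
    "ActRecord",
    "ObservationRecord",
    "EmrDataset",
    "DatasetFormatError",
    "read_dataset",
    "write_dataset",
    "sort_dataset",
    "DRUG_CLASSES",
    "ASTHMA_TREATMENT_CLASSES",
    "CODE_SYSTEMS",
    "SEX_LEVELS",
    "SMOKING_VALUES",
]

SEX_LEVELS = ("male", "female", "unknown")
CODE_SYSTEMS = ("ICD9", "ICD10", "SNOMED")
DRUG_CLASSES = (
    "SABA",
    "SAMA",
    "SABA_SAMA",
    "ICS",
    "ICS_LABA",
    "LABA",
    "LAMA",
    "LTRA",
    "MAST_CELL",
    "METHYLXANTHINE",
    "BIOLOGIC",
    "OCS",
    "OTHER",
)
#: classes counting as "asthma treatment" for the treated-cohort criterion.
#: OCS is assumed to be short-course (supply <= 28 days) and OTHER is any
#: non-asthma drug; neither qualifies a patient as "treated".
ASTHMA_TREATMENT_CLASSES = frozenset(DRUG_CLASSES) - {"OCS", "OTHER"}
OBSERVATION_KINDS = ("smoking_status", "bmi")
SMOKING_VALUES = ("current smoker", "former smoker", "non-smoker")
ETHNICITY_VALUES = ("hispanic", "non_hispanic")
STRENGTH_UNITS = ("mcg", "mg")


class DatasetFormatError(ValueError):
    """Raised when an exchange file violates the documented dialect."""


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    birth_year: Optional[int]
    sex: str
    # demographic observations: patients may carry several dated race /
    # ethnicity entries, possibly conflicting; derivation handles conflicts.
    race_entries: tuple = ()
    ethnicity_entries: tuple = ()


@dataclass(frozen=True)
class EncounterRecord:
    patient_id: str
    date: datetime.date
    provider_specialty: Optional[str] = None


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    date: datetime.date
    code_system: str
    code: str


@dataclass(frozen=True)
class PrescriptionRecord:
    patient_id: str
    date: datetime.date
    ndc: str
    generic_name: str
    ingredients: tuple
    drug_class: str
    strength_value: Optional[float] = None
    strength_unit: Optional[str] = None
    sig_frequency_per_day: Optional[float] = None
    sig_dose_amount: Optional[float] = None
    sig_dose_unit: Optional[str] = None


@dataclass(frozen=True)
class ActRecord:
    patient_id: str
    date: datetime.date
    items: tuple  # exactly 5 slots, each int in [1, 5] or None


@dataclass(frozen=True)
class ObservationRecord:
    patient_id: str
    date: datetime.date
    kind: str  # smoking_status | bmi
    value: object  # str for smoking, float kg/m^2 for bmi


@dataclass
class EmrDataset:
    patients: list = field(default_factory=list)
    encounters: list = field(default_factory=list)
    diagnoses: list = field(default_factory=list)
    prescriptions: list = field(default_factory=list)
    act_records: list = field(default_factory=list)
    observations: list = field(default_factory=list)

    def validate(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise DatasetFormatError("duplicate patient_id in patients table")
        known = set(ids)
        for name in ("encounters", "diagnoses", "prescriptions", "act_records", "observations"):
            for rec in getattr(self, name):
                if rec.patient_id not in known:
                    raise DatasetFormatError(
                        f"{name}: patient_id {rec.patient_id!r} not present in patients table"
                    )


FILE_NAMES = {
    "patients": "patients.csv",
    "encounters": "encounters.csv",
    "diagnoses": "diagnoses.csv",
    "prescriptions": "prescriptions.csv",
    "act_records": "act_records.csv",
    "observations": "observations.csv",
}

HEADERS = {
    "patients": ["patient_id", "birth_year", "sex", "race_entries", "ethnicity_entries"],
    "encounters": ["patient_id", "date", "provider_specialty"],
    "diagnoses": ["patient_id", "date", "code_system", "code"],
    "prescriptions": [
        "patient_id",
        "date",
        "ndc",
        "generic_name",
        "ingredients",
        "drug_class",
        "strength_value",
        "strength_unit",
        "sig_frequency_per_day",
        "sig_dose_amount",
        "sig_dose_unit",
    ],
    "act_records": ["patient_id", "date", "item1", "item2", "item3", "item4", "item5"],
    "observations": ["patient_id", "date", "kind", "value"],
}


# --- cell-level parsing -------------------------------------------------

def _parse_date(cell: str) -> datetime.date:
    return datetime.date.fromisoformat(cell)


def _opt(cell: str) -> Optional[str]:
    return cell if cell != "" else None


def _opt_int(cell: str) -> Optional[int]:
    return int(cell) if cell != "" else None


def _opt_float(cell: str) -> Optional[float]:
    return float(cell) if cell != "" else None


def _pos(value, label):
    if value is not None and not value > 0:
        raise DatasetFormatError(f"{label} must be > 0, got {value}")
    return value


def _enum(cell: str, allowed, label):
    if cell not in allowed:
        raise DatasetFormatError(f"{label} must be one of {sorted(allowed)}, got {cell!r}")
    return cell


def _parse_entries(cell: str) -> tuple:
    """Parse 'date:value|date:value' packed demographic entries."""
    if cell == "":
        return ()
    out = []
    for chunk in cell.split("|"):
        d, _, v = chunk.partition(":")
        if not v:
            raise DatasetFormatError(f"malformed entry {chunk!r}")
        out.append((_parse_date(d), v))
    return tuple(out)


def _format_entries(entries: Iterable) -> str:
    return "|".join(f"{d.isoformat()}:{v}" for d, v in entries)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, datetime.date):
        return value.isoformat()
    return str(value)


# --- row parsers --------------------------------------------------------

def _parse_patient(row) -> PatientRecord:
    pid = row["patient_id"]
    if pid == "":
        raise DatasetFormatError("patient_id must be non-empty")
    ents = _parse_entries(row["ethnicity_entries"])
    for _, v in ents:
        _enum(v, ETHNICITY_VALUES, "ethnicity entry")
    return PatientRecord(
        patient_id=pid,
        birth_year=_opt_int(row["birth_year"]),
        sex=_enum(row["sex"], SEX_LEVELS, "sex"),
        race_entries=_parse_entries(row["race_entries"]),
        ethnicity_entries=ents,
    )


def _parse_encounter(row) -> EncounterRecord:
    return EncounterRecord(
        patient_id=row["patient_id"],
        date=_parse_date(row["date"]),
        provider_specialty=_opt(row["provider_specialty"]),
    )


def _parse_diagnosis(row) -> DiagnosisRecord:
    code = row["code"]
    if code == "":
        raise DatasetFormatError("diagnosis code must be non-empty")
    return DiagnosisRecord(
        patient_id=row["patient_id"],
        date=_parse_date(row["date"]),
        code_system=_enum(row["code_system"], CODE_SYSTEMS, "code_system"),
        code=code,
    )


def _parse_prescription(row) -> PrescriptionRecord:
    unit = _opt(row["strength_unit"])
    if unit is not None:
        _enum(unit, STRENGTH_UNITS, "strength_unit")
    return PrescriptionRecord(
        patient_id=row["patient_id"],
        date=_parse_date(row["date"]),
        ndc=row["ndc"],
        generic_name=row["generic_name"],
        ingredients=tuple(row["ingredients"].split("|")) if row["ingredients"] else (),
        drug_class=_enum(row["drug_class"], DRUG_CLASSES, "drug_class"),
        strength_value=_pos(_opt_float(row["strength_value"]), "strength_value"),
        strength_unit=unit,
        sig_frequency_per_day=_pos(_opt_float(row["sig_frequency_per_day"]), "sig_frequency_per_day"),
        sig_dose_amount=_pos(_opt_float(row["sig_dose_amount"]), "sig_dose_amount"),
        sig_dose_unit=_opt(row["sig_dose_unit"]),
    )


def _parse_act(row) -> ActRecord:
    items = []
    for k in ("item1", "item2", "item3", "item4", "item5"):
        v = _opt_int(row[k])
        if v is not None and not 1 <= v <= 5:
            raise DatasetFormatError(f"ACT item {k} out of range [1,5]: {v}")
        items.append(v)
    return ActRecord(patient_id=row["patient_id"], date=_parse_date(row["date"]), items=tuple(items))


def _parse_observation(row) -> ObservationRecord:
    kind = _enum(row["kind"], OBSERVATION_KINDS, "kind")
    if kind == "bmi":
        value = float(row["value"])
        if not 5 < value < 150:
            raise DatasetFormatError(f"bmi out of plausible range (5,150): {value}")
    else:
        value = _enum(row["value"], SMOKING_VALUES, "smoking value")
    return ObservationRecord(
        patient_id=row["patient_id"], date=_parse_date(row["date"]), kind=kind, value=value
    )


_PARSERS = {
    "patients": _parse_patient,
    "encounters": _parse_encounter,
    "diagnoses": _parse_diagnosis,
    "prescriptions": _parse_prescription,
    "act_records": _parse_act,
    "observations": _parse_observation,
}


def read_dataset(directory_path) -> EmrDataset:
    """Read the six named CSV files from *directory_path* into an EmrDataset.

    Missing cells become ``None``.  A missing file raises
    :class:`FileNotFoundError` naming the file; malformed cells are collected
    into a row-indexed report and raised as :class:`DatasetFormatError`.
    """
    directory_path = Path(directory_path)
    dataset = EmrDataset()
    errors = []
    for table, fname in FILE_NAMES.items():
        path = directory_path / fname
        if not path.exists():
            raise FileNotFoundError(f"required file missing: {path}")
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing_cols = [c for c in HEADERS[table] if c not in frame.columns]
        if missing_cols:
            raise DatasetFormatError(f"{fname}: missing columns {missing_cols}")
        parser = _PARSERS[table]
        records = getattr(dataset, table)
        for i, row in enumerate(frame.to_dict("records")):
            try:
                records.append(parser(row))
            except (ValueError, KeyError) as exc:
                errors.append(f"{fname} row {i}: {exc}")
    if errors:
        raise DatasetFormatError("unparseable rows:\n" + "\n".join(errors))
    dataset.validate()
    return dataset


def _row_patients(r: PatientRecord):
    return [r.patient_id, _fmt(r.birth_year), r.sex, _format_entries(r.race_entries), _format_entries(r.ethnicity_entries)]


def _row_encounters(r: EncounterRecord):
    return [r.patient_id, _fmt(r.date), _fmt(r.provider_specialty)]


def _row_diagnoses(r: DiagnosisRecord):
    return [r.patient_id, _fmt(r.date), r.code_system, r.code]


def _row_prescriptions(r: PrescriptionRecord):
    return [
        r.patient_id,
        _fmt(r.date),
        r.ndc,
        r.generic_name,
        "|".join(r.ingredients),
        r.drug_class,
        _fmt(r.strength_value),
        _fmt(r.strength_unit),
        _fmt(r.sig_frequency_per_day),
        _fmt(r.sig_dose_amount),
        _fmt(r.sig_dose_unit),
    ]


def _row_act(r: ActRecord):
    return [r.patient_id, _fmt(r.date)] + [_fmt(v) for v in r.items]


def _row_observations(r: ObservationRecord):
    return [r.patient_id, _fmt(r.date), r.kind, _fmt(r.value)]


_FORMATTERS = {
    "patients": _row_patients,
    "encounters": _row_encounters,
    "diagnoses": _row_diagnoses,
    "prescriptions": _row_prescriptions,
    "act_records": _row_act,
    "observations": _row_observations,
}


def sort_dataset(dataset: EmrDataset) -> EmrDataset:
    """Return a copy in canonical order: by patient_id, then date (stable)."""
    def key(rec):
        return (rec.patient_id, getattr(rec, "date", datetime.date.min))

    return EmrDataset(**{
        name: sorted(getattr(dataset, name), key=key) for name in FILE_NAMES
    })


def write_dataset(dataset: EmrDataset, directory_path) -> Path:
    """Write the six CSV files with canonical headers and deterministic order."""
    dataset.validate()
    directory_path = Path(directory_path)
    directory_path.mkdir(parents=True, exist_ok=True)
    canonical = sort_dataset(dataset)
    for table, fname in FILE_NAMES.items():
        fmt = _FORMATTERS[table]
        rows = [fmt(rec) for rec in getattr(canonical, table)]
        frame = pd.DataFrame(rows, columns=HEADERS[table], dtype=object)
        frame.to_csv(directory_path / fname, index=False)
    return directory_path
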