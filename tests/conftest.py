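import datetime

import pytest

from asthmactl.data_model import (
    ActRecord,
    DiagnosisRecord,
    EmrDataset,
    EncounterRecord,
    ObservationRecord,
    PatientRecord,
    PrescriptionRecord,
)

INDEX = datetime.date(2016, 6, 15)


def day(offset: int, anchor: datetime.date = INDEX) -> datetime.date:
    """Date *offset* days after the default index anchor (negative = before)."""
    return anchor + datetime.timedelta(days=offset)


def mk_act(items=(4, 4, 4, 4, 4), date=INDEX, pid="P1"):
    return ActRecord(patient_id=pid, date=date, items=tuple(items))


def mk_rx(
    drug_class="SABA",
    date=day(-60),
    pid="P1",
    ndc="N1",
    generic_name="drug",
    ingredients=("albuterol",),
    strength_value=90.0,
    strength_unit="mcg",
    freq=2.0,
    amount=2.0,
    dose_unit="puff",
):
    return PrescriptionRecord(
        patient_id=pid,
        date=date,
        ndc=ndc,
        generic_name=generic_name,
        ingredients=tuple(ingredients),
        drug_class=drug_class,
        strength_value=strength_value,
        strength_unit=strength_unit,
        sig_frequency_per_day=freq,
        sig_dose_amount=amount,
        sig_dose_unit=dose_unit,
    )


def mk_ics(strength=110.0, date=day(-60), freq=2.0, amount=2.0, ingredient="fluticasone propionate", ndc="ICS1", pid="P1"):
    return mk_rx(
        drug_class="ICS",
        date=date,
        pid=pid,
        ndc=ndc,
        generic_name=ingredient,
        ingredients=(ingredient,),
        strength_value=strength,
        freq=freq,
        amount=amount,
    )


def mk_patient(pid="P1", birth_year=1980, sex="female", race_entries=(), ethnicity_entries=()):
    return PatientRecord(
        patient_id=pid,
        birth_year=birth_year,
        sex=sex,
        race_entries=tuple(race_entries),
        ethnicity_entries=tuple(ethnicity_entries),
    )


def single_patient_dataset(
    pid="P1",
    acts=None,
    rxs=None,
    diagnoses=None,
    encounters=None,
    observations=None,
    birth_year=1980,
):
    """A minimal dataset for one patient that passes every inclusion stage
    unless a field is overridden."""
    if acts is None:
        acts = [mk_act(pid=pid)]
    if rxs is None:
        rxs = [mk_rx(pid=pid, date=day(-60))]
    if diagnoses is None:
        diagnoses = [DiagnosisRecord(pid, day(-300), "ICD10", "J45.909")]
    if encounters is None:
        encounters = [
            EncounterRecord(pid, day(-200), "Family Medicine"),
            EncounterRecord(pid, INDEX, "Family Medicine"),
        ]
    if observations is None:
        observations = []
    return EmrDataset(
        patients=[mk_patient(pid=pid, birth_year=birth_year)],
        encounters=list(encounters),
        diagnoses=list(diagnoses),
        prescriptions=list(rxs),
        act_records=list(acts),
        observations=list(observations),
    )


@pytest.fixture
def thresholds():
    from asthmactl.gina import load_dose_thresholds

    return load_dose_thresholds()
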