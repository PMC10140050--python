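"""Synthetic EMR generator with planted ground truth.

Emulates the structure the analysis assumes in a primary-care EMR extract:
each "clean" patient carries an asthma diagnosis predating index, database
activity at least 182 days before index, prescriptions inside the exposure
window realizing a planted GINA step, an index ACT whose score realizes a
planted control status, and demographic/clinical observations realizing
planted covariates.  Noise patients violate exactly one inclusion criterion
each, recorded in the ground truth, so the attrition stages are verifiable.

The planted outcome is log-linear in the covariates: the probability of
not-well-controlled asthma is exp(intercept + step and covariate effects),
so true prevalence ratios are exactly the exponentiated coefficients and
parameter-recovery experiments have a known truth.  Configurations whose
linear predictor can exceed probability 1 are rejected at validation rather
than clamped (clamping would silently bias recovery).

Default step shares and covariate distributions approximate the descriptive
structure of a large US outpatient asthma population (treated patients,
ages 12-88, ~30% not well-controlled overall, obesity increasing with
treatment step).  Covariates are sampled independently within step; the
joint distribution of a real population is not emulated.

Everything is deterministic given the seed: one pseudo-random stream is
split per patient by counter, so records do not depend on generation order.
"""

from __future__ import annotations

import datetime
import importlib.resources
import itertools
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .data_model import (
    ActRecord,
    DiagnosisRecord,
    EmrDataset,
    EncounterRecord,
    ObservationRecord,
    PatientRecord,
    PrescriptionRecord,
    sort_dataset,
)

__all__ = [
    "SimConfig",
    "OutcomeModel",
    "SimConfigError",
    "generate",
    "sample_cohort",
    "decompose_score",
    "load_catalog",
    "EXCLUSION_REASONS",
    "STEP_LABELS",
]

STEP_LABELS = ("1", "2", "3", "4", "5", "undefined")
EXCLUSION_REASONS = (
    "no_asthma_dx",
    "no_valid_act",
    "untreated",
    "insufficient_activity",
    "copd",
    "missing_birth_year",
)
#: attrition-stage label corresponding to each planted exclusion reason
REASON_TO_STAGE = {
    "no_asthma_dx": "asthma_diagnosis",
    "no_valid_act": "valid_index_act",
    "untreated": "treated_in_exposure_window",
    "insufficient_activity": "activity_182d_before_index",
    "copd": "no_copd_diagnosis",
    "missing_birth_year": "birth_year_present",
}

#: age the outcome model's age effect is centered on (years)
AGE_CENTER = 44


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class OutcomeModel:
    """Log-linear model for P(not well-controlled): log p = intercept + effects.

    Coefficients are log prevalence ratios; the age effect is per year,
    centered at AGE_CENTER so the intercept is the reference-profile
    prevalence at age 44.
    """

    intercept: float = float(np.log(0.25))
    step: dict = field(
        default_factory=lambda: {
            "2": float(np.log(0.857)),
            "3": float(np.log(0.962)),
            "4": float(np.log(1.160)),
            "5": float(np.log(1.529)),
            "undefined": float(np.log(1.113)),
        }
    )
    age_per_year: float = 0.004
    smoking: dict = field(
        default_factory=lambda: {"former": 0.10, "current": 0.30, "unknown": 0.0}
    )
    bmi_category: dict = field(
        default_factory=lambda: {
            "underweight": 0.10,
            "overweight": 0.05,
            "obese": 0.20,
            "unknown": -0.05,
        }
    )
    race: dict = field(default_factory=dict)
    ethnicity: dict = field(default_factory=dict)
    visit_type: dict = field(default_factory=dict)

    def linear_predictor(self, step, age, smoking, bmi_category, race, ethnicity, visit_type):
        return (
            self.intercept
            + self.step.get(step, 0.0)
            + self.age_per_year * (age - AGE_CENTER)
            + self.smoking.get(smoking, 0.0)
            + self.bmi_category.get(bmi_category, 0.0)
            + self.race.get(race, 0.0)
            + self.ethnicity.get(ethnicity, 0.0)
            + self.visit_type.get(visit_type, 0.0)
        )

    def max_probability(self) -> float:
        lp = self.intercept
        lp += max([0.0] + list(self.step.values()))
        lp += max(
            self.age_per_year * (12 - AGE_CENTER), self.age_per_year * (88 - AGE_CENTER)
        )
        for block in (self.smoking, self.bmi_category, self.race, self.ethnicity, self.visit_type):
            lp += max([0.0] + list(block.values()))
        return float(np.exp(lp))


# Per-step marginal covariate distributions (probabilities normalized at use).
_AGE_BY_STEP = {
    "1": (39.4, 21.8), "2": (44.1, 22.7), "3": (43.9, 22.7),
    "4": (49.3, 20.6), "5": (55.9, 16.6), "undefined": (54.9, 19.5),
}
_MALE_BY_STEP = {"1": 0.371, "2": 0.349, "3": 0.360, "4": 0.348, "5": 0.358, "undefined": 0.378}
_HISPANIC_BY_STEP = {"1": 0.214, "2": 0.181, "3": 0.195, "4": 0.201, "5": 0.091, "undefined": 0.171}
_ETHNICITY_MISSING = 0.05
_RACE_BY_STEP = {  # white, african_american, other, unknown
    "1": (0.440, 0.176, 0.079, 0.306),
    "2": (0.497, 0.148, 0.075, 0.280),
    "3": (0.433, 0.184, 0.092, 0.292),
    "4": (0.467, 0.166, 0.082, 0.285),
    "5": (0.388, 0.182, 0.036, 0.394),
    "undefined": (0.472, 0.150, 0.109, 0.269),
}
_SMOKING_BY_STEP = {  # non_smoker, former, current, unknown
    "1": (0.645, 0.117, 0.123, 0.115),
    "2": (0.714, 0.121, 0.065, 0.101),
    "3": (0.678, 0.140, 0.079, 0.103),
    "4": (0.662, 0.154, 0.095, 0.088),
    "5": (0.545, 0.206, 0.115, 0.133),
    "undefined": (0.591, 0.202, 0.135, 0.073),
}
_BMI_BY_STEP = {  # underweight, normal, overweight, obese, unknown
    "1": (0.019, 0.179, 0.219, 0.394, 0.189),
    "2": (0.019, 0.176, 0.227, 0.403, 0.175),
    "3": (0.015, 0.195, 0.217, 0.409, 0.164),
    "4": (0.014, 0.167, 0.240, 0.491, 0.088),
    "5": (0.006, 0.127, 0.267, 0.545, 0.055),
    "undefined": (0.036, 0.202, 0.254, 0.440, 0.067),
}
_VISIT_BY_STEP = {  # primary_care, specialist, other, unknown
    "1": (0.570, 0.106, 0.310, 0.015),
    "2": (0.550, 0.219, 0.218, 0.013),
    "3": (0.484, 0.267, 0.235, 0.014),
    "4": (0.552, 0.316, 0.119, 0.013),
    "5": (0.394, 0.558, 0.036, 0.012),
    "undefined": (0.627, 0.264, 0.083, 0.026),
}
_RACE_LEVELS = ("white", "african_american", "other", "unknown")
_SMOKING_LEVELS = ("non_smoker", "former", "current", "unknown")
_BMI_LEVELS = ("underweight", "normal", "overweight", "obese", "unknown")
_VISIT_LEVELS = ("primary_care", "specialist", "other", "unknown")

#: overall step mixture (Step 1..5, Undefined)
DEFAULT_STEP_PROBS = (0.345, 0.241, 0.140, 0.251, 0.011, 0.012)


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 2000
    seed: int = 0
    step_probs: tuple = DEFAULT_STEP_PROBS
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    #: per-reason fractions of patients planted to violate one criterion
    exclusion_noise: dict = field(
        default_factory=lambda: {r: 0.02 for r in EXCLUSION_REASONS}
    )
    #: fraction of ICS-containing prescriptions with a blanked sig field
    missing_sig_fraction: float = 0.10

    def validate(self) -> None:
        if self.n_patients < 0:
            raise SimConfigError("n_patients must be >= 0")
        if len(self.step_probs) != 6:
            raise SimConfigError("step_probs must have 6 entries (Step 1..5, Undefined)")
        if abs(sum(self.step_probs) - 1.0) > 1e-9:
            raise SimConfigError(f"step_probs must sum to 1, got {sum(self.step_probs)}")
        if any(p < 0 for p in self.step_probs):
            raise SimConfigError("step_probs must be non-negative")
        pmax = self.outcome_model.max_probability()
        if pmax > 1.0:
            raise SimConfigError(
                f"outcome model admits probability {pmax:.3f} > 1; "
                "shrink the intercept or the effects"
            )
        noise_total = sum(self.exclusion_noise.values())
        unknown = set(self.exclusion_noise) - set(EXCLUSION_REASONS)
        if unknown:
            raise SimConfigError(f"unknown exclusion reasons: {sorted(unknown)}")
        if noise_total > 1 or any(v < 0 for v in self.exclusion_noise.values()):
            raise SimConfigError("exclusion_noise fractions must be >= 0 and sum <= 1")
        if not 0 <= self.missing_sig_fraction <= 1:
            raise SimConfigError("missing_sig_fraction must be in [0,1]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(open(path).read()) or {}
        kwargs = {}
        for key in ("n_patients", "seed", "missing_sig_fraction"):
            if key in raw:
                kwargs[key] = raw[key]
        if "step_probs" in raw:
            kwargs["step_probs"] = tuple(raw["step_probs"])
        if "exclusion_noise" in raw:
            kwargs["exclusion_noise"] = dict(raw["exclusion_noise"])
        if "outcome_model" in raw:
            om = raw["outcome_model"]
            kwargs["outcome_model"] = OutcomeModel(
                **{k: (dict(v) if isinstance(v, dict) else v) for k, v in om.items()}
            )
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


# --- ACT item decomposition ---------------------------------------------

_ALL_ITEM_TUPLES = tuple(itertools.product(range(1, 6), repeat=5))
_TUPLES_BY_SUM = {
    total: tuple(t for t in _ALL_ITEM_TUPLES if sum(t) == total) for total in range(5, 26)
}


def decompose_score(total: int, rng: np.random.Generator) -> tuple:
    """A uniformly random 5-item composition of *total* (items each 1-5)."""
    if not 5 <= total <= 25:
        raise ValueError(f"ACT total out of range [5,25]: {total}")
    options = _TUPLES_BY_SUM[total]
    return options[int(rng.integers(len(options)))]


# --- catalog ------------------------------------------------------------

def load_catalog(path=None) -> dict:
    """NDC -> product description (identity, class, strength, canonical sig)."""
    if path is None:
        text = (importlib.resources.files("asthmactl.data") / "medications.yaml").read_text()
    else:
        text = open(path).read()
    return yaml.safe_load(text)


_CATALOG = load_catalog()

NDC = {
    "saba": "00001-0001",
    "sama": "00001-0002",
    "saba_sama": "00001-0003",
    "flu44": "00002-0044",
    "flu110": "00002-0110",
    "flu220": "00002-0220",
    "bud90": "00002-0090",
    "bud180": "00002-0180",
    "budsusp": "00002-0500",
    "fs100": "00003-0100",
    "fs250": "00003-0250",
    "fs500": "00003-0500",
    "bf80": "00003-0080",
    "bf160": "00003-0160",
    "laba": "00004-0050",
    "lama": "00005-0018",
    "ltra": "00006-0010",
    "mast": "00007-0800",
    "methyl": "00008-0300",
    "biologic": "00009-0100",
    "ocs": "00010-0010",
    "other": "00011-0500",
}

# Regimen menu realizing each planted step; entries are lists of catalog keys.
# "open" marks an open ICS + LABA combination generated 0-15 days apart.
_STEP_REGIMENS = {
    "1": [["saba"], ["saba", "sama"], ["saba_sama"]],
    "2": [["flu44"], ["bud90"], ["ltra"]],
    "3": [["fs100"], ["bf80"], ["flu110"], ["budsusp"], ["open:flu44+laba"]],
    "4": [["fs250"], ["fs500"], ["bf160"], ["flu220"], ["flu110", "ltra"]],
    "5": [["fs250", "biologic"], ["fs500", "biologic"], ["bf160", "biologic"]],
    "undefined": [["laba"]],
}
_ICS_BEARING = {"ICS", "ICS_LABA"}


def _make_rx(pid, date, key, blank_field=None) -> PrescriptionRecord:
    ndc = NDC[key] if key in NDC else key
    prod = _CATALOG[ndc]
    rec = PrescriptionRecord(
        patient_id=pid,
        date=date,
        ndc=ndc,
        generic_name=prod["generic_name"],
        ingredients=tuple(prod["ingredients"]),
        drug_class=prod["drug_class"],
        strength_value=float(prod["strength_value"]),
        strength_unit=prod["strength_unit"],
        sig_frequency_per_day=float(prod["frequency"]),
        sig_dose_amount=float(prod["dose_amount"]),
        sig_dose_unit=prod["dose_unit"],
    )
    if blank_field is not None:
        rec = replace(rec, **{blank_field: None})
    return rec


# --- cohort-level sampling (fast path, no records) ----------------------

def sample_cohort(config: SimConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Sample planted steps, covariates and outcomes for n patients.

    Vectorized; returns one row per patient with the planted analysis
    attributes (no EMR records).  ``generate`` builds records realizing
    these rows; parameter-recovery experiments can fit the model on this
    frame directly.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, 2**20])
    n = config.n_patients
    steps = rng.choice(STEP_LABELS, size=n, p=np.asarray(config.step_probs))
    age = np.empty(n, dtype=int)
    sex = np.empty(n, dtype=object)
    race = np.empty(n, dtype=object)
    ethnicity = np.empty(n, dtype=object)
    smoking = np.empty(n, dtype=object)
    bmi_cat = np.empty(n, dtype=object)
    visit = np.empty(n, dtype=object)
    for s in STEP_LABELS:
        m = steps == s
        k = int(m.sum())
        if k == 0:
            continue
        mean, sd = _AGE_BY_STEP[s]
        a, b = (12 - mean) / sd, (88 - mean) / sd
        age[m] = np.round(
            stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=k, random_state=rng)
        ).astype(int)
        sex[m] = np.where(rng.random(k) < _MALE_BY_STEP[s], "male", "female")
        race[m] = rng.choice(_RACE_LEVELS, size=k, p=_norm(_RACE_BY_STEP[s]))
        eth_draw = rng.random(k)
        p_his = _HISPANIC_BY_STEP[s] * (1 - _ETHNICITY_MISSING)
        ethnicity[m] = np.where(
            eth_draw < p_his,
            "hispanic",
            np.where(eth_draw < p_his + _ETHNICITY_MISSING, "missing", "non_hispanic"),
        )
        smoking[m] = rng.choice(_SMOKING_LEVELS, size=k, p=_norm(_SMOKING_BY_STEP[s]))
        bmi_cat[m] = rng.choice(_BMI_LEVELS, size=k, p=_norm(_BMI_BY_STEP[s]))
        visit[m] = rng.choice(_VISIT_LEVELS, size=k, p=_norm(_VISIT_BY_STEP[s]))

    om = config.outcome_model
    lp = np.full(n, om.intercept)
    lp += np.array([om.step.get(s, 0.0) for s in steps])
    lp += om.age_per_year * (age - AGE_CENTER)
    for block, values in (
        (om.smoking, smoking),
        (om.bmi_category, bmi_cat),
        (om.race, race),
        (om.ethnicity, ethnicity),
        (om.visit_type, visit),
    ):
        if block:
            lp += np.array([block.get(v, 0.0) for v in values])
    p = np.exp(lp)
    outcome = rng.random(n) < p

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "planted_step": steps,
            "planted_control_status": np.where(
                outcome, "not_well_controlled", "well_controlled"
            ),
            "age_years": age,
            "sex": sex,
            "race": race,
            "ethnicity": ethnicity,
            "smoking": smoking,
            "bmi_category": bmi_cat,
            "visit_type": visit,
        }
    )


def _norm(p):
    p = np.asarray(p, dtype=float)
    return p / p.sum()


# --- full record-level generation ---------------------------------------

_PRIMARY_SPECIALTIES = ("Family Medicine", "Internal Medicine", "General Medicine")
_SPECIALIST_SPECIALTIES = ("Allergy and Immunology", "Pulmonary Disease", "Emergency Medicine")
_OTHER_SPECIALTIES = ("Dermatology", "Cardiology", "Orthopedics")
_OTHER_RACES = ("asian", "american indian", "native hawaiian")

_INDEX_EARLIEST = datetime.date(2016, 7, 1)
_INDEX_SPAN_DAYS = 364  # index dates uniform over one mid-study year


def generate(config: SimConfig):
    """Generate (EmrDataset, GroundTruth frame) realizing *config*.

    Ground truth columns: planted step/control/covariates and
    planted_exclusion_reason ('none' for patients intended to survive every
    filter).  Deterministic given the seed; tables are returned in canonical
    sorted order so a write/read round trip is the identity.
    """
    config.validate()
    cohort = sample_cohort(config)
    n = len(cohort)

    reasons = np.full(n, "none", dtype=object)
    if n and config.exclusion_noise:
        r_assign = np.random.default_rng([config.seed, 2**20 + 1]).random(n)
        edges = np.cumsum([config.exclusion_noise.get(r, 0.0) for r in EXCLUSION_REASONS])
        for i, reason in enumerate(EXCLUSION_REASONS):
            lo = 0.0 if i == 0 else edges[i - 1]
            reasons[(r_assign >= lo) & (r_assign < edges[i])] = reason

    dataset = EmrDataset()
    truth_rows = []
    ndcs_with_complete_sig = set()
    for i in range(n):
        row = cohort.iloc[i]
        rng = np.random.default_rng([config.seed, i])
        _emit_patient(dataset, row, reasons[i], config, rng, ndcs_with_complete_sig, truth_rows)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id",
            "planted_step",
            "planted_control_status",
            "planted_act_score",
            "age_years",
            "sex",
            "race",
            "ethnicity",
            "smoking",
            "bmi_category",
            "visit_type",
            "planted_exclusion_reason",
        ],
    )
    return sort_dataset(dataset), truth


def _emit_patient(dataset, row, reason, config, rng, complete_sig_seen, truth_rows):
    pid = row["patient_id"]
    step = row["planted_step"]
    index = _INDEX_EARLIEST + datetime.timedelta(days=int(rng.integers(_INDEX_SPAN_DAYS + 1)))

    # --- ACT record(s) and outcome
    not_well = row["planted_control_status"] == "not_well_controlled"
    score = int(rng.integers(5, 20)) if not_well else int(rng.integers(20, 26))
    items = decompose_score(score, rng)
    acts = []
    if reason == "no_valid_act":
        mech = int(rng.integers(3))
        if mech == 0:  # one item missing
            broken = list(items)
            broken[int(rng.integers(5))] = None
            acts.append(ActRecord(pid, index, tuple(broken)))
        elif mech == 1:  # same-day duplicate, both complete
            acts.append(ActRecord(pid, index, items))
            acts.append(ActRecord(pid, index, decompose_score(score, rng)))
        else:  # incomplete first, complete repeat 1-27 days later
            broken = list(items)
            broken[int(rng.integers(5))] = None
            acts.append(ActRecord(pid, index, tuple(broken)))
            later = index + datetime.timedelta(days=int(rng.integers(1, 28)))
            acts.append(ActRecord(pid, later, items))
    else:
        acts.append(ActRecord(pid, index, items))
    dataset.act_records.extend(acts)

    # --- diagnoses
    if reason != "no_asthma_dx":
        system, code = [("ICD10", "J45.909"), ("ICD9", "493.90"), ("SNOMED", "H3312")][
            int(rng.integers(3))
        ]
        dx_date = index - datetime.timedelta(days=int(rng.integers(250, 601)))
        dataset.diagnoses.append(DiagnosisRecord(pid, dx_date, system, code))
    if rng.random() < 0.3:  # unrelated comorbidity
        dataset.diagnoses.append(
            DiagnosisRecord(pid, index - datetime.timedelta(days=int(rng.integers(1, 400))), "ICD10", "I10")
        )
    if reason == "copd":
        copd_code = ["J44.9", "J43.9", "J41.0"][int(rng.integers(3))]
        dataset.diagnoses.append(
            DiagnosisRecord(pid, index - datetime.timedelta(days=int(rng.integers(1, 201))), "ICD10", copd_code)
        )

    # --- encounters: long-ago activity + index-day visit
    if reason == "insufficient_activity":
        activity_date = index - datetime.timedelta(days=100)
    else:
        activity_date = index - datetime.timedelta(days=int(rng.integers(182, 421)))
    dataset.encounters.append(
        EncounterRecord(pid, activity_date, _PRIMARY_SPECIALTIES[int(rng.integers(3))])
    )
    visit = row["visit_type"]
    if visit == "primary_care":
        spec = _PRIMARY_SPECIALTIES[int(rng.integers(3))]
    elif visit == "specialist":
        spec = _SPECIALIST_SPECIALTIES[int(rng.integers(3))]
    elif visit == "other":
        spec = _OTHER_SPECIALTIES[int(rng.integers(3))]
    else:
        spec = None  # encounter recorded without a specialty
    dataset.encounters.append(EncounterRecord(pid, index, spec))

    # --- prescriptions realizing the planted step
    def window_date():
        return index - datetime.timedelta(days=int(rng.integers(29, 211)))

    rx_keys: list = []
    if reason == "untreated":
        dataset.prescriptions.append(
            _make_rx(pid, index - datetime.timedelta(days=int(rng.integers(1, 29))), "saba")
        )
    else:
        menu = _STEP_REGIMENS[step]
        regimen = menu[int(rng.integers(len(menu)))]
        near_date = index - datetime.timedelta(days=int(rng.integers(29, 121)))
        for key in regimen:
            if key.startswith("open:"):
                ics_key, laba_key = key[5:].split("+")
                gap = int(rng.integers(-15, 16))
                laba_date = near_date + datetime.timedelta(days=gap)
                laba_date = min(max(laba_date, index - datetime.timedelta(days=210)),
                                index - datetime.timedelta(days=29))
                _emit_rx(dataset, pid, near_date, ics_key, config, rng, complete_sig_seen)
                _emit_rx(dataset, pid, laba_date, laba_key, config, rng, complete_sig_seen)
            else:
                _emit_rx(dataset, pid, near_date, key, config, rng, complete_sig_seen)
                rx_keys.append(key)
        # decoy: an earlier, lower-intensity ICS that nearest-to-index
        # selection must ignore
        if (
            step in ("3", "4")
            and rx_keys
            and _CATALOG[NDC[rx_keys[0]]]["drug_class"] in _ICS_BEARING
            and rng.random() < 0.3
        ):
            decoy_date = index - datetime.timedelta(days=int(rng.integers(150, 211)))
            decoy = "flu44" if _CATALOG[NDC[rx_keys[0]]]["drug_class"] == "ICS" else "fs100"
            _emit_rx(dataset, pid, decoy_date, decoy, config, rng, complete_sig_seen)
        if step != "1" and rng.random() < 0.7:  # reliever alongside controllers
            dataset.prescriptions.append(_make_rx(pid, window_date(), "saba"))
        if rng.random() < 0.15:  # short-course OCS, never affects step
            dataset.prescriptions.append(_make_rx(pid, window_date(), "ocs"))
        if rng.random() < 0.3:  # non-asthma drug
            dataset.prescriptions.append(_make_rx(pid, window_date(), "other"))

    # --- observations realizing covariates
    smoking = row["smoking"]
    if smoking == "current":
        dataset.observations.append(
            ObservationRecord(pid, index - datetime.timedelta(days=int(rng.integers(0, 30))), "smoking_status", "current smoker")
        )
        if rng.random() < 0.3:
            dataset.observations.append(
                ObservationRecord(pid, index - datetime.timedelta(days=int(rng.integers(60, 300))), "smoking_status", "former smoker")
            )
    elif smoking == "former":
        dataset.observations.append(
            ObservationRecord(pid, index - datetime.timedelta(days=int(rng.integers(60, 300))), "smoking_status", "former smoker")
        )
        if rng.random() < 0.5:  # later non-smoker entry must not override
            dataset.observations.append(
                ObservationRecord(pid, index - datetime.timedelta(days=int(rng.integers(0, 30))), "smoking_status", "non-smoker")
            )
    elif smoking == "non_smoker":
        for _ in range(1 + int(rng.integers(2))):
            dataset.observations.append(
                ObservationRecord(pid, index - datetime.timedelta(days=int(rng.integers(0, 300))), "smoking_status", "non-smoker")
            )
    elif rng.random() < 0.5:  # unknown: only a post-index record, ignored
        dataset.observations.append(
            ObservationRecord(pid, index + datetime.timedelta(days=int(rng.integers(1, 60))), "smoking_status", "non-smoker")
        )

    bmi_cat = row["bmi_category"]
    if bmi_cat != "unknown":
        lo, hi = {
            "underweight": (15.0, 18.4),
            "normal": (18.5, 24.9),
            "overweight": (25.0, 29.9),
            "obese": (30.0, 45.0),
        }[bmi_cat]
        value = round(float(lo + (hi - lo) * rng.random()), 1)
        dataset.observations.append(
            ObservationRecord(pid, index - datetime.timedelta(days=int(rng.integers(0, 60))), "bmi", value)
        )

    # --- patient record with demographic entries
    race = row["race"]
    if race == "unknown":
        if rng.random() < 0.5:  # conflicting entries
            race_entries = (
                (index - datetime.timedelta(days=400), "white"),
                (index - datetime.timedelta(days=100), "asian"),
            )
        else:
            race_entries = ()
    else:
        raw = {
            "white": "white",
            "african_american": "black/african american",
        }.get(race) or _OTHER_RACES[int(rng.integers(3))]
        race_entries = tuple(
            (index - datetime.timedelta(days=int(rng.integers(1, 500))), raw)
            for _ in range(1 + int(rng.integers(2)))
        )
    ethnicity = row["ethnicity"]
    if ethnicity == "missing":
        eth_entries = ()
    else:
        eth_entries = ((index - datetime.timedelta(days=int(rng.integers(1, 500))), ethnicity),)

    birth_year = None if reason == "missing_birth_year" else index.year - int(row["age_years"])
    dataset.patients.append(
        PatientRecord(
            patient_id=pid,
            birth_year=birth_year,
            sex=row["sex"],
            race_entries=race_entries,
            ethnicity_entries=eth_entries,
        )
    )

    truth_rows.append(
        {
            "patient_id": pid,
            "planted_step": step,
            "planted_control_status": row["planted_control_status"],
            "planted_act_score": score,
            "age_years": int(row["age_years"]),
            "sex": row["sex"],
            "race": race,
            "ethnicity": ethnicity,
            "smoking": smoking,
            "bmi_category": bmi_cat,
            "visit_type": row["visit_type"],
            "planted_exclusion_reason": reason,
        }
    )


def _emit_rx(dataset, pid, date, key, config, rng, complete_sig_seen):
    """Emit one prescription, possibly blanking a sig field on ICS products.

    A field is blanked only when a complete same-NDC prescription has
    already been emitted, so the per-NDC mode imputation always has a donor
    and planted steps stay recoverable.
    """
    ndc = NDC[key]
    blank = None
    if (
        _CATALOG[ndc]["drug_class"] in _ICS_BEARING
        and ndc in complete_sig_seen
        and rng.random() < config.missing_sig_fraction
    ):
        blank = ("sig_frequency_per_day", "sig_dose_amount")[int(rng.integers(2))]
    rec = _make_rx(pid, date, key, blank_field=blank)
    if blank is None:
        complete_sig_seen.add(ndc)
    dataset.prescriptions.append(rec)
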