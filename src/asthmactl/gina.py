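"""GINA treatment-step classification from exposure-window prescriptions.

The GINA (Global Initiative for Asthma) 2018 guidelines tier asthma
treatment into five steps of increasing intensity.  A patient's step is
inferred here from the medication classes prescribed in the exposure window
and, for ICS-containing regimens, the inhaled-corticosteroid daily dose:

    daily dose [mcg/day] = frequency/day x dose amount x strength [mcg]

Sig fields extracted from free-text prescription instructions (frequency,
dose amount, dose unit) may be missing; missing values are imputed with the
mode of the field among prescriptions sharing the same NDC, ties broken to
the smallest value.  mg strengths are converted to mcg before the product.

Separate ICS and LABA prescriptions dated within 30 days of each other
(inclusive) form an "open" ICS/LABA combination; farther apart, the ICS is
treated as ICS-only and the LABA is ignored.  When several ICS or ICS/LABA
prescriptions fall in the window, only those closest to the index date
contribute the dose: equidistant same-ingredient prescriptions have their
daily doses summed (same-day refills), different-ingredient ties take the
highest resulting dose level.

Short-acting relievers (SABA, SAMA, SABA/SAMA combinations) collapse to a
single reliever flag and never alter a controller-defined step.  OCS is
assumed short-course (supply <= 28 days) and never affects the step.
Profiles missing information the rules need, or with combinations that match
no step (LABA or LAMA monotherapy, OCS only, nothing prescribed), are
classified Undefined.
"""

from __future__ import annotations

import datetime
import importlib.resources
from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Optional

import yaml

from .data_model import PrescriptionRecord

__all__ = [
    "DoseThresholdTable",
    "DoseComponent",
    "MedProfile",
    "GinaAssignment",
    "load_dose_thresholds",
    "impute_sig_fields",
    "ics_daily_dose",
    "pair_open_combo",
    "build_med_profile",
    "assign_step",
    "classify_patient",
    "STEPS",
    "DOSE_LEVELS",
    "OPEN_COMBO_DAYS",
]

STEPS = ("1", "2", "3", "4", "5", "undefined")
DOSE_LEVELS = ("low", "medium", "high")
_LEVEL_RANK = {"low": 0, "medium": 1, "high": 2}
#: maximum day gap (inclusive) for an open ICS + LABA combination
OPEN_COMBO_DAYS = 30

RELIEVER_CLASSES = {"SABA", "SAMA", "SABA_SAMA"}


@dataclass(frozen=True)
class DoseThresholdTable:
    """Per-ingredient low/medium daily-dose upper bounds in mcg/day.

    dose <= low_max -> low; <= medium_max -> medium; above -> high.
    Doses below any stated floor are still "low": the step rules only need
    the three-level split.
    """

    bounds: dict  # ingredient -> (low_max, medium_max)

    def __post_init__(self):
        for ing, (lo, hi) in self.bounds.items():
            if not 0 < lo <= hi:
                raise ValueError(f"invalid thresholds for {ing!r}: ({lo}, {hi})")

    def level(self, ingredient: str, daily_dose_mcg: float) -> Optional[str]:
        b = self.bounds.get(ingredient.lower())
        if b is None:
            return None
        lo, hi = b
        if daily_dose_mcg <= lo:
            return "low"
        if daily_dose_mcg <= hi:
            return "medium"
        return "high"


def load_dose_thresholds(path=None) -> DoseThresholdTable:
    """Load the ingredient dose-threshold table (ships a GINA-2018 default)."""
    if path is None:
        text = (
            importlib.resources.files("asthmactl.data") / "dose_thresholds.yaml"
        ).read_text()
    else:
        text = open(path).read()
    raw = yaml.safe_load(text)
    bounds = {
        str(k).lower(): (float(v["low_max"]), float(v["medium_max"]))
        for k, v in raw.items()
    }
    return DoseThresholdTable(bounds=bounds)


@dataclass(frozen=True)
class DoseComponent:
    ingredient: str
    daily_dose_mcg: Optional[float]
    level: Optional[str]  # low | medium | high | None (unknown)


@dataclass(frozen=True)
class MedProfile:
    has_saba_class: bool = False
    ics_component: Optional[DoseComponent] = None
    icslaba_component: Optional[DoseComponent] = None
    has_laba_mono: bool = False
    has_lama: bool = False
    has_ltra: bool = False
    has_mast_cell: bool = False
    has_methylxanthine: bool = False
    has_biologic: bool = False
    has_ocs: bool = False
    dose_indeterminate: bool = False


@dataclass(frozen=True)
class GinaAssignment:
    step: str
    rationale: tuple


# --- sig-field imputation ----------------------------------------------

_SIG_FIELDS = ("sig_frequency_per_day", "sig_dose_amount", "sig_dose_unit")


def _mode_smallest(values):
    counts = Counter(values)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def impute_sig_fields(prescriptions) -> list:
    """Replace missing sig fields by the per-NDC mode over the whole table.

    Each of the three fields is imputed independently; an NDC with no
    non-missing value for a field leaves that field missing.  Mode ties are
    broken to the smallest value (deterministic, and conservative for dose).
    """
    modes: dict = {}
    for f in _SIG_FIELDS:
        per_ndc: dict = {}
        for rx in prescriptions:
            v = getattr(rx, f)
            if v is not None:
                per_ndc.setdefault(rx.ndc, []).append(v)
        modes[f] = {ndc: _mode_smallest(vals) for ndc, vals in per_ndc.items()}
    out = []
    for rx in prescriptions:
        updates = {
            f: modes[f][rx.ndc]
            for f in _SIG_FIELDS
            if getattr(rx, f) is None and rx.ndc in modes[f]
        }
        out.append(replace(rx, **updates) if updates else rx)
    return out


def ics_daily_dose(
    frequency_per_day, dose_amount, strength_value, strength_unit
) -> Optional[float]:
    """(frequency) x (dose amount) x (strength in mcg); None if any input missing."""
    if frequency_per_day is None or dose_amount is None or strength_value is None:
        return None
    if strength_unit == "mg":
        strength_mcg = strength_value * 1000.0
    elif strength_unit == "mcg":
        strength_mcg = strength_value
    else:
        return None
    return frequency_per_day * dose_amount * strength_mcg


def pair_open_combo(ics_rx: PrescriptionRecord, laba_rxs) -> bool:
    """True iff some LABA prescription is dated within 30 days (inclusive)."""
    return any(
        abs((ics_rx.date - laba.date).days) <= OPEN_COMBO_DAYS for laba in laba_rxs
    )


# --- profile construction ----------------------------------------------

def _ics_ingredient(rx: PrescriptionRecord, thresholds: DoseThresholdTable):
    for ing in rx.ingredients:
        if ing.lower() in thresholds.bounds:
            return ing.lower()
    return None


def _select_component(rxs, index_date, thresholds):
    """Nearest-to-index dose component from a pool of ICS-bearing rxs.

    Returns (component, indeterminate).  Among the prescriptions tied for
    the smallest day distance to index: same-ingredient doses are summed,
    different ingredients resolve to the highest level.
    """
    if not rxs:
        return None, False
    best = min(abs((index_date - rx.date).days) for rx in rxs)
    nearest = [rx for rx in rxs if abs((index_date - rx.date).days) == best]
    per_ingredient: dict = {}
    for rx in nearest:
        ing = _ics_ingredient(rx, thresholds)
        dose = ics_daily_dose(
            rx.sig_frequency_per_day, rx.sig_dose_amount, rx.strength_value, rx.strength_unit
        )
        if ing is None or dose is None:
            name = ing or (rx.ingredients[0].lower() if rx.ingredients else rx.generic_name)
            return DoseComponent(ingredient=name, daily_dose_mcg=None, level=None), True
        per_ingredient[ing] = per_ingredient.get(ing, 0.0) + dose
    candidates = [
        DoseComponent(ing, dose, thresholds.level(ing, dose))
        for ing, dose in sorted(per_ingredient.items())
    ]
    return max(candidates, key=lambda c: _LEVEL_RANK[c.level]), False


def build_med_profile(window_rxs, index_date: datetime.date, thresholds: DoseThresholdTable) -> MedProfile:
    """Summarize one patient's exposure-window prescriptions (post-imputation)."""
    by_class: dict = {}
    for rx in window_rxs:
        by_class.setdefault(rx.drug_class, []).append(rx)

    labas = by_class.get("LABA", [])
    combo_pool = list(by_class.get("ICS_LABA", []))
    ics_pool = []
    for rx in by_class.get("ICS", []):
        (combo_pool if pair_open_combo(rx, labas) else ics_pool).append(rx)

    ics_component, ind1 = _select_component(ics_pool, index_date, thresholds)
    icslaba_component, ind2 = _select_component(combo_pool, index_date, thresholds)

    has_ics_any = bool(by_class.get("ICS") or by_class.get("ICS_LABA"))
    return MedProfile(
        has_saba_class=any(c in by_class for c in RELIEVER_CLASSES),
        ics_component=ics_component,
        icslaba_component=icslaba_component,
        has_laba_mono=bool(labas) and not has_ics_any,
        has_lama="LAMA" in by_class,
        has_ltra="LTRA" in by_class,
        has_mast_cell="MAST_CELL" in by_class,
        has_methylxanthine="METHYLXANTHINE" in by_class,
        has_biologic="BIOLOGIC" in by_class,
        has_ocs="OCS" in by_class,
        dose_indeterminate=ind1 or ind2,
    )


# --- step rules ---------------------------------------------------------

def _rules(p: MedProfile, ics: Optional[str], combo: Optional[str]):
    """Step for resolved dose levels; ics/combo are levels or None if absent."""
    if p.has_biologic:
        return "5", "biologic add-on therapy"
    if combo in ("medium", "high"):
        return "4", f"{combo}-dose ICS/LABA"
    if ics == "high":
        return "4", "high-dose ICS"
    if p.has_lama and (ics is not None or combo is not None):
        return "4", "LAMA add-on to ICS-containing therapy"
    if ics == "medium" and (p.has_ltra or p.has_methylxanthine):
        return "4", "medium-dose ICS plus LTRA/methylxanthine"
    if combo == "low":
        return "3", "low-dose ICS/LABA"
    if ics == "medium":
        return "3", "medium-dose ICS"
    if ics == "low" and (p.has_ltra or p.has_methylxanthine):
        return "3", "low-dose ICS plus LTRA/methylxanthine"
    if ics == "low":
        return "2", "low-dose ICS"
    if ics is None and combo is None and not p.has_lama and not p.has_laba_mono:
        singles = (p.has_ltra, p.has_mast_cell, p.has_methylxanthine)
        if sum(singles) == 1:
            which = ("LTRA", "mast-cell stabilizer", "methylxanthine")[singles.index(True)]
            return "2", f"{which} as sole controller"
    controllers = (
        ics is not None
        or combo is not None
        or p.has_laba_mono
        or p.has_lama
        or p.has_ltra
        or p.has_mast_cell
        or p.has_methylxanthine
    )
    if p.has_saba_class and not controllers:
        return "1", "reliever (SABA class) only"
    return "undefined", "no clear GINA regimen"


def assign_step(profile: MedProfile) -> GinaAssignment:
    """Map a medication profile to a GINA step (total function).

    Components with an unknown dose level are resolved by evaluating the
    rules under every low/high substitution: if all substitutions agree the
    common step is returned, otherwise the dose ambiguity makes the step
    Undefined.
    """
    rationale = []
    unknown = []
    if profile.ics_component is not None and profile.ics_component.level is None:
        unknown.append("ics")
    if profile.icslaba_component is not None and profile.icslaba_component.level is None:
        unknown.append("combo")

    def resolved(subs: dict):
        ics = profile.ics_component.level if profile.ics_component else None
        combo = profile.icslaba_component.level if profile.icslaba_component else None
        return subs.get("ics", ics), subs.get("combo", combo)

    if not unknown:
        step, why = _rules(profile, *resolved({}))
        rationale.append(why)
    else:
        outcomes = set()
        why = ""
        for combo_levels in product(("low", "high"), repeat=len(unknown)):
            subs = dict(zip(unknown, combo_levels))
            step, why = _rules(profile, *resolved(subs))
            outcomes.add(step)
        if len(outcomes) == 1:
            step = outcomes.pop()
            rationale.append(why + " (dose level not needed)")
        else:
            step = "undefined"
            rationale.append("ICS daily dose indeterminate and required by the rules")
    if profile.has_saba_class and step != "1":
        rationale.append("reliever use allowed alongside controllers")
    if profile.has_ocs:
        rationale.append("OCS assumed short-course; no effect on step")
    return GinaAssignment(step=step, rationale=tuple(rationale))


def classify_patient(window_rxs, index_date, thresholds) -> GinaAssignment:
    """Profile + step assignment in one call (prescriptions must be imputed)."""
    return assign_step(build_med_profile(window_rxs, index_date, thresholds))
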