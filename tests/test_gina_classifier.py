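"""Sig imputation, ICS daily dose, open combinations, and the step rules."""

import dataclasses

import pytest

from asthmactl.gina import (
    DoseComponent,
    MedProfile,
    assign_step,
    build_med_profile,
    ics_daily_dose,
    impute_sig_fields,
    pair_open_combo,
)

from conftest import INDEX, day, mk_ics, mk_rx


class TestImputation:
    def _rxs(self, freqs, ndc="X"):
        return [mk_rx(ndc=ndc, freq=f) for f in freqs]

    def test_mode_fills_missing(self):
        rxs = self._rxs([2.0, 2.0, 1.0, None])
        out = impute_sig_fields(rxs)
        assert out[3].sig_frequency_per_day == 2.0

    def test_all_missing_stays_missing(self):
        out = impute_sig_fields(self._rxs([None, None]))
        assert all(r.sig_frequency_per_day is None for r in out)

    def test_bimodal_tie_breaks_to_smallest(self):
        out = impute_sig_fields(self._rxs([1.0, 1.0, 2.0, 2.0, None]))
        assert out[4].sig_frequency_per_day == 1.0

    def test_mode_is_per_ndc_over_whole_table(self):
        rxs = self._rxs([4.0, 4.0], ndc="A") + self._rxs([2.0, None], ndc="B")
        out = impute_sig_fields(rxs)
        assert out[3].sig_frequency_per_day == 2.0  # B's own mode, not A's

    def test_fields_imputed_independently(self):
        rxs = [mk_rx(ndc="C", freq=None, amount=3.0), mk_rx(ndc="C", freq=2.0, amount=None)]
        out = impute_sig_fields(rxs)
        assert out[0].sig_frequency_per_day == 2.0
        assert out[1].sig_dose_amount == 3.0


class TestDailyDose:
    @pytest.mark.parametrize(
        "freq, amount, strength, unit, expected",
        [
            (2, 2, 110, "mcg", 440.0),
            (1, 1, 250, "mcg", 250.0),
            (2, 1, 0.25, "mg", 500.0),  # mg converted to mcg first
        ],
    )
    def test_product_formula(self, freq, amount, strength, unit, expected):
        assert ics_daily_dose(freq, amount, strength, unit) == expected

    @pytest.mark.parametrize("missing", ["freq", "amount", "strength"])
    def test_missing_input_signals_indeterminate(self, missing):
        args = {"freq": 2, "amount": 2, "strength": 110}
        args[missing] = None
        assert ics_daily_dose(args["freq"], args["amount"], args["strength"], "mcg") is None


class TestOpenCombo:
    @pytest.mark.parametrize("gap, paired", [(25, True), (30, True), (31, False), (45, False), (-30, True)])
    def test_30_day_boundary_inclusive(self, gap, paired):
        ics = mk_ics(date=day(-100))
        laba = mk_rx(drug_class="LABA", ingredients=("salmeterol",), date=day(-100 + gap))
        assert pair_open_combo(ics, [laba]) is paired


class TestMedProfile:
    def test_saba_only(self, thresholds):
        p = build_med_profile([mk_rx(drug_class="SABA")], INDEX, thresholds)
        assert p.has_saba_class and p.ics_component is None and not p.dose_indeterminate

    def test_nearest_prescription_contributes_dose(self, thresholds):
        far = mk_ics(strength=220.0, date=day(-200), ndc="I220")
        near = mk_ics(strength=44.0, date=day(-40), ndc="I44")
        p = build_med_profile([far, near], INDEX, thresholds)
        assert p.ics_component.daily_dose_mcg == 176.0
        assert p.ics_component.level == "low"

    def test_equidistant_same_ingredient_doses_sum(self, thresholds):
        a = mk_ics(strength=110.0, date=day(-40))
        b = mk_ics(strength=110.0, date=day(-40))
        p = build_med_profile([a, b], INDEX, thresholds)
        assert p.ics_component.daily_dose_mcg == 880.0
        assert p.ics_component.level == "high"

    def test_equidistant_different_ingredients_take_max_level(self, thresholds):
        flu = mk_ics(strength=44.0, date=day(-40))  # 176 -> low
        bud = mk_ics(strength=180.0, date=day(-40), ingredient="budesonide", ndc="B")  # 720 -> medium
        p = build_med_profile([flu, bud], INDEX, thresholds)
        assert p.ics_component.ingredient == "budesonide"
        assert p.ics_component.level == "medium"

    def test_open_combo_becomes_icslaba_component(self, thresholds):
        ics = mk_ics(strength=44.0, date=day(-60))
        laba = mk_rx(drug_class="LABA", ingredients=("salmeterol",), date=day(-40))
        p = build_med_profile([ics, laba], INDEX, thresholds)
        assert p.icslaba_component is not None and p.ics_component is None
        assert not p.has_laba_mono

    def test_distant_laba_leaves_ics_only(self, thresholds):
        ics = mk_ics(strength=44.0, date=day(-150))
        laba = mk_rx(drug_class="LABA", ingredients=("salmeterol",), date=day(-40))
        p = build_med_profile([ics, laba], INDEX, thresholds)
        assert p.ics_component is not None and p.icslaba_component is None
        assert not p.has_laba_mono  # LABA ignored, not monotherapy

    def test_unimputable_dose_marks_indeterminate(self, thresholds):
        ics = mk_ics(freq=None)
        p = build_med_profile([ics], INDEX, thresholds)
        assert p.dose_indeterminate and p.ics_component.level is None

    def test_unknown_ingredient_marks_indeterminate(self, thresholds):
        ics = mk_ics(ingredient="flunisolide")  # not in the threshold table
        p = build_med_profile([ics], INDEX, thresholds)
        assert p.dose_indeterminate


def comp(level, ingredient="fluticasone propionate", dose=200.0):
    return DoseComponent(ingredient=ingredient, daily_dose_mcg=dose, level=level)


class TestAssignStep:
    @pytest.mark.parametrize(
        "profile, step",
        [
            (MedProfile(has_saba_class=True), "1"),
            (MedProfile(), "undefined"),  # nothing prescribed
            (MedProfile(ics_component=comp("low")), "2"),
            (MedProfile(has_ltra=True), "2"),
            (MedProfile(has_mast_cell=True), "2"),
            (MedProfile(has_methylxanthine=True), "2"),
            (MedProfile(has_ltra=True, has_methylxanthine=True), "undefined"),  # unclear combo
            (MedProfile(icslaba_component=comp("low"), has_saba_class=True), "3"),
            (MedProfile(ics_component=comp("medium")), "3"),
            (MedProfile(ics_component=comp("low"), has_ltra=True), "3"),
            (MedProfile(icslaba_component=comp("medium")), "4"),
            (MedProfile(icslaba_component=comp("high")), "4"),
            (MedProfile(ics_component=comp("high")), "4"),
            (MedProfile(ics_component=comp("medium"), has_ltra=True), "4"),
            (MedProfile(ics_component=comp("low"), has_lama=True), "4"),
            (MedProfile(icslaba_component=comp("high"), has_biologic=True), "5"),
            (MedProfile(has_biologic=True), "5"),
            (MedProfile(has_laba_mono=True), "undefined"),
            (MedProfile(has_lama=True), "undefined"),  # LAMA without ICS
            (MedProfile(has_ocs=True), "undefined"),  # OCS only
            (MedProfile(ics_component=comp(None, dose=None), dose_indeterminate=True), "undefined"),
        ],
    )
    def test_rule_table(self, profile, step):
        assert assign_step(profile).step == step

    def test_saba_sama_collapse_to_reliever(self, thresholds):
        p = build_med_profile(
            [mk_rx(drug_class="SABA"), mk_rx(drug_class="SAMA", ndc="S2")], INDEX, thresholds
        )
        assert assign_step(p).step == "1"

    def test_unknown_dose_resolved_when_level_not_needed(self):
        # LAMA + any ICS is Step 4 whatever the dose turns out to be
        p = MedProfile(ics_component=comp(None, dose=None), has_lama=True, dose_indeterminate=True)
        assert assign_step(p).step == "4"

    def test_rationale_is_nonempty(self):
        a = assign_step(MedProfile(has_saba_class=True, has_ocs=True))
        assert a.rationale and any("OCS" in r for r in a.rationale)
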