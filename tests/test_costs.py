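"""Cost model: event costs, continuing costs, payers, productivity."""

import dataclasses

import numpy as np
import pytest

from osteocost.costs import (
    PAYERS,
    PathwayParams,
    PayerLedger,
    UnitCostTable,
    annual_continuing_cost,
    build_state_cost_profile,
    hip_event_cost,
    productivity_cost,
    vertebral_event_cost,
    wrist_event_cost,
)
from osteocost.markov import DiscountSpec, discount_factor
from osteocost.states import POST_STATES, State


def zero_units() -> UnitCostTable:
    kwargs = {
        f.name: 0.0
        for f in dataclasses.fields(UnitCostTable)
        if f.name not in ("currency", "base_year", "daily_wage")
    }
    kwargs["daily_wage"] = {g: {b: 0.0 for b in ("50-54", "55-59", "60-64", "65+")}
                            for g in ("male", "female")}
    return UnitCostTable(**kwargs)


def zero_paths() -> PathwayParams:
    return PathwayParams(
        wrist_surgery_frac=0.0,
        wrist_physio_frac=0.0,
        vertebral_hospital_frac=0.0,
        vertebral_gp_frac=0.0,
        vertebral_undiagnosed_frac=1.0,
        hip_fixation_frac_male=0.0,
        hip_fixation_frac_female=0.0,
        standard_rehab_frac=0.0,
        respite_frac=0.0,
        nursing_home_incremental_frac=0.0,
        food_service_frac=0.0,
        device_uptake=(0.0,) * 8,
        gp_incremental_frac=0.0,
        personal_care_incremental_frac=0.0,
        persistence=(0.0,),
        participation_rate=0.0,
    )


class TestPayerLedger:
    def test_total_is_exact_sum(self):
        ledger = PayerLedger(regional=1.25, municipal=2.5, patient=0.25)
        assert ledger.total == pytest.approx(4.0, abs=1e-9)
        assert sum(ledger.as_dict().values()) == ledger.total

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            PayerLedger(regional=-1.0)

    def test_addition_and_scaling(self):
        a = PayerLedger(regional=1.0, patient=2.0)
        b = PayerLedger(municipal=3.0)
        c = (a + b).scaled(2.0)
        assert c.regional == 2.0 and c.patient == 4.0 and c.municipal == 6.0


class TestWristEvent:
    def test_zero_inputs_zero_ledger(self):
        ledger = wrist_event_cost("male", zero_units(), zero_paths())
        assert ledger.total == 0.0

    def test_default_hospital_component(self):
        # 0.25 * 2189.01 + 0.75 * 224.40 + 350.27
        ledger = wrist_event_cost("male", UnitCostTable(), PathwayParams())
        assert ledger.regional == pytest.approx(1_065.82, abs=0.005)

    def test_all_surgical_boundary(self):
        path = dataclasses.replace(PathwayParams(), wrist_surgery_frac=1.0)
        ledger = wrist_event_cost("female", UnitCostTable(), path)
        assert ledger.regional == pytest.approx(2_189.01 + 350.27, abs=1e-9)

    def test_physiotherapy_is_municipal(self):
        # 0.25 referred * 5 one-hour sessions at the rehab hourly rate
        ledger = wrist_event_cost("male", UnitCostTable(), PathwayParams())
        assert ledger.municipal == pytest.approx(0.25 * 5 * 113.84, abs=1e-9)


class TestVertebralEvent:
    def test_all_undiagnosed_is_free(self):
        path = PathwayParams(
            vertebral_hospital_frac=0.0, vertebral_gp_frac=0.0, vertebral_undiagnosed_frac=1.0
        )
        assert vertebral_event_cost("female", UnitCostTable(), path).total == 0.0

    def test_default_hospital_component(self):
        # 0.10 * (0.5 * 7507.24 + 0.5 * 3176.01) = 534.16, plus DXA for
        # the diagnosed half
        ledger = vertebral_event_cost("male", UnitCostTable(), PathwayParams())
        hospital_part = ledger.regional - 0.5 * 350.27
        assert hospital_part == pytest.approx(534.16, abs=0.005)

    def test_gp_branch_pays_gp_and_patient(self):
        unit = UnitCostTable()
        ledger = vertebral_event_cost("female", unit, PathwayParams())
        assert ledger.general_practice == pytest.approx(0.40 * 175.82, abs=1e-9)
        # pain relief charged fully to the patient
        assert ledger.patient == pytest.approx(0.40 * unit.pain_relief_annual, abs=1e-9)

    def test_bad_split_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PathwayParams(vertebral_hospital_frac=0.3, vertebral_gp_frac=0.3,
                          vertebral_undiagnosed_frac=0.3)


class TestHipEvent:
    def test_pathways_off_leaves_surgery_and_dxa(self):
        path = zero_paths()
        ledger = hip_event_cost("male", UnitCostTable(), path)
        # fixation fraction 0 -> all alloplastic
        assert ledger.regional == pytest.approx(9_216.89 + 350.27, abs=1e-9)
        assert ledger.municipal == 0.0 and ledger.patient == 0.0

    def test_rehabilitation_component(self):
        # 0.963 * 2 h/wk * 13 wk * 113.84/h, municipal
        expected = 0.963 * 2 * 13 * 113.84
        base = hip_event_cost("male", UnitCostTable(), zero_paths()).municipal
        path = dataclasses.replace(zero_paths(), standard_rehab_frac=0.963)
        ledger = hip_event_cost("male", UnitCostTable(), path)
        assert ledger.municipal - base == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(2_850.326, abs=0.001)

    def test_respite_component_split_between_municipal_and_patient(self):
        path = dataclasses.replace(zero_paths(), respite_frac=0.05)
        ledger = hip_event_cost("female", UnitCostTable(), path)
        assert ledger.municipal == pytest.approx(0.05 * 26.8 * 112.09, abs=1e-9)  # 150.20
        assert ledger.patient == pytest.approx(0.05 * 26.8 * 15.82, abs=1e-9)  # 21.20

    def test_gender_specific_fixation_mix(self):
        unit = UnitCostTable()
        male = hip_event_cost("male", unit, PathwayParams())
        female = hip_event_cost("female", unit, PathwayParams())
        fix_tariff = 0.5 * 9_945.17 + 0.5 * 6_327.75
        expected_m = 0.823 * fix_tariff + 0.177 * 9_216.89
        expected_f = 0.754 * fix_tariff + 0.246 * 9_216.89
        devices = sum(
            getattr(unit, f) for f in UnitCostTable.DEVICE_FIELDS
        )
        assert male.regional == pytest.approx(expected_m + 350.27 + 0.25 * devices, abs=1e-6)
        assert female.regional == pytest.approx(expected_f + 350.27 + 0.25 * devices, abs=1e-6)

    def test_device_bundle_split_25_75(self):
        unit = UnitCostTable()
        devices = sum(getattr(unit, f) for f in UnitCostTable.DEVICE_FIELDS)
        assert devices == pytest.approx(563.16, abs=1e-9)
        base = hip_event_cost("male", unit, zero_paths())
        path = dataclasses.replace(zero_paths(), device_uptake=(1.0,) * 8)
        ledger = hip_event_cost("male", unit, path)
        assert ledger.regional - base.regional == pytest.approx(0.25 * devices, abs=1e-9)
        assert ledger.municipal - base.municipal == pytest.approx(0.75 * devices, abs=1e-9)


class TestContinuing:
    def test_zero_persistence_and_fractions_zero_ledger(self):
        path = zero_paths()
        for s in POST_STATES:
            assert annual_continuing_cost(s, "male", UnitCostTable(), path).total == 0.0

    def test_pharma_split_with_full_persistence(self):
        path = dataclasses.replace(zero_paths(), persistence=(1.0,))
        ledger = annual_continuing_cost(State.POST_WRIST, "male", UnitCostTable(), path)
        assert ledger.regional == pytest.approx(0.75 * 332.53, abs=1e-9)  # 249.40
        assert ledger.patient == pytest.approx(0.25 * 332.53, abs=1e-9)  # 83.13

    def test_personal_care_only_in_post_hip_states(self):
        # 0.166 * 3.7 h/wk * 52 wk * 62.26/h
        expected = 0.166 * 3.7 * 52 * 62.26
        assert expected == pytest.approx(1_988.485, abs=0.001)
        unit, path = UnitCostTable(), PathwayParams()
        hip = annual_continuing_cost(State.POST_FIRST_HIP, "female", unit, path)
        wrist = annual_continuing_cost(State.POST_WRIST, "female", unit, path)
        assert hip.municipal == pytest.approx(expected, abs=1e-9)
        assert wrist.municipal == 0.0

    def test_well_continuing_opt_in(self):
        unit = UnitCostTable()
        off = annual_continuing_cost(State.WELL, "male", unit, PathwayParams())
        assert off.total == 0.0
        path = dataclasses.replace(PathwayParams(), well_continuing=True)
        on = annual_continuing_cost(State.WELL, "male", unit, path)
        assert on.total > 0.0 and on.municipal == 0.0

    def test_fracture_and_death_states_cost_nothing(self):
        unit, path = UnitCostTable(), PathwayParams()
        for s in (State.WRIST, State.FIRST_HIP, State.DEATH):
            assert annual_continuing_cost(s, "male", unit, path).total == 0.0


class TestProductivity:
    def test_zero_past_retirement(self):
        unit, path = UnitCostTable(), PathwayParams()
        for event in ("wrist", "vertebral", "hip", "death"):
            assert productivity_cost(event, "male", 70, unit, path) == 0.0
            assert productivity_cost(event, "female", 65, unit, path) == 0.0

    def test_wrist_male_full_participation(self):
        path = dataclasses.replace(PathwayParams(), participation_rate=1.0)
        # 1 absence day at the male 50-54 daily wage
        assert productivity_cost("wrist", "male", 52, UnitCostTable(), path) == pytest.approx(
            219.96
        )

    def test_vertebral_female_full_participation(self):
        path = dataclasses.replace(PathwayParams(), participation_rate=1.0)
        # 4 absence days at the female 60-64 daily wage
        assert productivity_cost("vertebral", "female", 62, UnitCostTable(), path) == (
            pytest.approx(4 * 133.16)
        )

    def test_death_is_discounted_wage_stream_to_65(self):
        path = dataclasses.replace(PathwayParams(), participation_rate=1.0,
                                   work_days_per_year=200.0)
        unit = UnitCostTable()
        spec = DiscountSpec(0.03)
        got = productivity_cost("death", "female", 62, unit, path, spec)
        expected = sum(
            unit.wage("female", t) * 200.0 * discount_factor(spec, t - 62) for t in (62, 63, 64)
        )
        assert got == pytest.approx(expected, abs=1e-9)

    def test_participation_scales_linearly(self):
        unit = UnitCostTable()
        full = productivity_cost("hip", "male", 55, unit,
                                 dataclasses.replace(PathwayParams(), participation_rate=1.0))
        a_75 = productivity_cost("hip", "male", 55, unit, PathwayParams())
        assert a_75 == pytest.approx(0.75 * full)


class TestProfile:
    def test_zero_units_give_zero_profile(self):
        profile = build_state_cost_profile("male", zero_units(), zero_paths())
        assert np.all(profile.event == 0) and np.all(profile.continuing == 0)

    def test_event_equals_independent_recomputation(self, epi):
        profile = build_state_cost_profile("female", UnitCostTable(), PathwayParams(), epi=epi)
        unit, path = UnitCostTable(), PathwayParams()
        age = 58
        # independent recomputation of the first-hip event ledger
        base = hip_event_cost("female", unit, path)
        prod = productivity_cost("hip", "female", age, unit, path)
        gi, ai = 1, age - 50
        rr = epi.rr_death[int(State.POST_FIRST_HIP)]
        excess = (1 - np.exp(-epi.mortality[gi, ai] * rr)) - (1 - np.exp(-epi.mortality[gi, ai]))
        prod += excess * productivity_cost("death", "female", age, unit, path)
        got = profile.event_ledger(age, State.FIRST_HIP)
        assert got.regional == pytest.approx(base.regional, abs=1e-9)
        assert got.municipal == pytest.approx(base.municipal, abs=1e-9)
        assert got.patient == pytest.approx(base.patient, abs=1e-9)
        assert got.productivity == pytest.approx(prod, abs=1e-9)

    def test_death_state_costs_nothing(self, epi):
        profile = build_state_cost_profile("male", UnitCostTable(), PathwayParams(), epi=epi)
        assert np.all(profile.event[:, int(State.DEATH)] == 0)
        assert np.all(profile.continuing[:, int(State.DEATH)] == 0)

    def test_payer_separation_municipal_change_leaves_regional(self):
        unit_hi = dataclasses.replace(UnitCostTable(), personal_care_hourly=1_000.0)
        a = build_state_cost_profile("male", UnitCostTable(), PathwayParams())
        b = build_state_cost_profile("male", unit_hi, PathwayParams())
        regional_idx = PAYERS.index("regional")
        assert np.array_equal(a.event[..., regional_idx], b.event[..., regional_idx])
        assert np.array_equal(a.continuing[..., regional_idx], b.continuing[..., regional_idx])

    def test_linearity_doubling_unit_costs_doubles_direct_ledgers(self):
        unit = UnitCostTable()
        doubled = dataclasses.replace(
            unit,
            **{
                f.name: 2 * getattr(unit, f.name)
                for f in dataclasses.fields(unit)
                if f.name not in ("currency", "base_year", "daily_wage")
            },
            daily_wage={g: {b: 2 * w for b, w in bands.items()}
                        for g, bands in unit.daily_wage.items()},
        )
        a = build_state_cost_profile("female", unit, PathwayParams())
        b = build_state_cost_profile("female", doubled, PathwayParams())
        assert np.allclose(b.event, 2 * a.event)
        assert np.allclose(b.continuing, 2 * a.continuing)

    def test_social_services_and_devices_only_in_hip_states(self):
        # zero every unit cost except social services and devices: only
        # hip-related states may carry any cost at all
        unit = zero_units()
        unit = dataclasses.replace(
            unit,
            personal_care_hourly=62.26,
            food_delivery_municipal=1.60,
            food_delivery_copay=6.30,
            device_walker=246.51,
        )
        profile = build_state_cost_profile("male", unit, PathwayParams())
        hip_related = {int(s) for s in
                       (State.FIRST_HIP, State.SECOND_HIP,
                        State.POST_FIRST_HIP, State.POST_SECOND_HIP)}
        for s in State:
            if int(s) in hip_related:
                continue
            assert np.all(profile.event[:, int(s)] == 0), s.label
            assert np.all(profile.continuing[:, int(s)] == 0), s.label
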