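"""Unit costs, care pathways, payer attribution and productivity losses.

Every euro the model spends originates here and is tagged with exactly
one payer: the region (hospital care, the reimbursed share of
pharmaceuticals, a quarter of assistive devices), general practice,
the municipality (rehabilitation, respite care, nursing home, social
services, three quarters of assistive devices), the patient
(co-payments and the unreimbursed pharmaceutical share), or
productivity (foregone wages, carried by employers and employees).

Costs come in two kinds: one-off *event* costs attached to the acute
fracture states at entry (surgery, diagnostics, rehabilitation,
discharge services, sick-day wage loss) and *continuing* annual costs
attached to the chronic post-fracture states (pharmaceutical
treatment, extra GP contact, and for post-hip states incremental
personal care).  Productivity losses are valued by the human-capital
approach: absence days — and, for fracture-attributable deaths before
retirement, the remaining wage stream to age 65 — at the average gross
daily wage for the person's gender and age band.

All default prices are in 2011 EUR.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .markov import DiscountSpec, N_STATES, discount_factor
from .states import (
    AGE_MIN,
    AGES,
    FRACTURE_STATES,
    MORTALITY_CONTEXT_OF,
    N_AGES,
    POST_STATES,
    State,
    wage_band,
)

__all__ = [
    "PAYERS",
    "PayerLedger",
    "UnitCostTable",
    "PathwayParams",
    "StateCostProfile",
    "wrist_event_cost",
    "vertebral_event_cost",
    "hip_event_cost",
    "annual_continuing_cost",
    "productivity_cost",
    "build_state_cost_profile",
]

PAYERS = ("regional", "general_practice", "municipal", "patient", "productivity")


@dataclass(frozen=True)
class PayerLedger:
    """A cost amount split by payer; supports addition and scaling."""

    regional: float = 0.0
    general_practice: float = 0.0
    municipal: float = 0.0
    patient: float = 0.0
    productivity: float = 0.0

    def __post_init__(self) -> None:
        for p in PAYERS:
            if getattr(self, p) < 0:
                raise ValueError(f"negative {p} amount")

    @property
    def total(self) -> float:
        return sum(getattr(self, p) for p in PAYERS)

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in PAYERS}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PAYERS])

    def __add__(self, other: "PayerLedger") -> "PayerLedger":
        return PayerLedger(**{p: getattr(self, p) + getattr(other, p) for p in PAYERS})

    def scaled(self, factor: float) -> "PayerLedger":
        return PayerLedger(**{p: getattr(self, p) * factor for p in PAYERS})


_DEFAULT_DAILY_WAGE = {
    "male": {"50-54": 219.96, "55-59": 211.51, "60-64": 186.60, "65+": 145.15},
    "female": {"50-54": 168.04, "55-59": 159.53, "60-64": 133.16, "65+": 102.08},
}


@dataclass
class UnitCostTable:
    """Unit prices feeding the cost model (2011 EUR).

    Defaults are Danish tariffs and averages: DRG tariffs for the
    surgical items, fee-schedule and reimbursement figures for GP and
    pharmaceuticals, municipal price lists for rehabilitation, respite
    and nursing-home care, social services and assistive devices, and
    gross daily wages by gender and age band.  ``pain_relief_annual``
    has no published tariff and carries a synthetic default.
    """

    currency: str = "EUR"
    base_year: int = 2011

    # hospital (regional) items
    wrist_orthopaedic: float = 2_189.01
    emergency_room: float = 224.40
    vertebral_pvp: float = 7_507.24  # percutaneous vertebroplasty
    vertebral_medical: float = 3_176.01
    hip_internal_fixation: float = 9_945.17
    hip_pertrochanteric_fixation: float = 6_327.75
    hip_alloplastic: float = 9_216.89
    dxa_scan: float = 350.27

    # primary care and pharmaceuticals
    gp_annual: float = 175.82
    pharma_annual_male: float = 332.53
    pharma_annual_female: float = 303.83
    pain_relief_annual: float = 40.00  # synthetic default; no published tariff

    # rehabilitation, respite, nursing home (municipal unless noted)
    rehab_hourly: float = 113.84
    rehab_home_hourly: float = 0.00
    respite_daily: float = 112.09
    respite_copay_daily: float = 15.82  # patient
    nursing_home_yearly: float = 51_858.98

    # social services
    food_delivery_municipal: float = 1.60
    food_delivery_copay: float = 6.30  # patient
    personal_care_hourly: float = 62.26

    # assistive devices (purchase prices)
    device_arthrodesis_cushion: float = 57.54
    device_bath_bench: float = 107.24
    device_bed_raiser: float = 19.30
    device_crutch: float = 19.71
    device_dressing_stick: float = 40.48
    device_reaching_aid: float = 13.40
    device_toilet_raiser: float = 58.98
    device_walker: float = 246.51

    # gross daily wage by gender and age band
    daily_wage: dict = field(default_factory=lambda: {
        g: dict(bands) for g, bands in _DEFAULT_DAILY_WAGE.items()
    })

    DEVICE_FIELDS = (
        "device_arthrodesis_cushion",
        "device_bath_bench",
        "device_bed_raiser",
        "device_crutch",
        "device_dressing_stick",
        "device_reaching_aid",
        "device_toilet_raiser",
        "device_walker",
    )

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and f.name != "base_year" and v < 0:
                raise ValueError(f"unit cost {f.name} must be >= 0")

    def device_prices(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.DEVICE_FIELDS])

    def pharma_annual(self, gender: str) -> float:
        return self.pharma_annual_male if gender == "male" else self.pharma_annual_female

    def wage(self, gender: str, age: int) -> float:
        return float(self.daily_wage[gender][wage_band(age)])


@dataclass
class PathwayParams:
    """Care-pathway fractions, durations and costing conventions.

    Treatment-mix fractions describe how an incident fracture is
    managed (e.g. the share of wrist fractures operated, the three-way
    split of vertebral fractures into hospital / GP / undiagnosed);
    incremental-use fractions describe the excess service use of
    fracture patients over the background population and so implement
    the incremental-cost perspective directly.
    """

    # wrist pathway
    wrist_surgery_frac: float = 0.25
    wrist_physio_frac: float = 0.25
    physio_sessions: float = 5.0  # 1-hour sessions, priced at the rehab hourly rate
    # vertebral pathway: hospital / GP / undiagnosed must sum to 1
    vertebral_hospital_frac: float = 0.10
    vertebral_gp_frac: float = 0.40
    vertebral_undiagnosed_frac: float = 0.50
    vertebral_pvp_mix: float = 0.5  # hospital share treated with vertebroplasty
    # hip pathway
    hip_fixation_frac_male: float = 0.823
    hip_fixation_frac_female: float = 0.754
    fixation_tariff_mix: float = 0.5  # split between the two internal-fixation tariffs
    standard_rehab_frac: float = 0.963  # remainder rehabilitates at home (zero tariff)
    rehab_hours_per_week: float = 2.0
    rehab_weeks: float = 13.0  # "3 months"
    respite_frac: float = 0.05
    respite_days: float = 26.8
    nursing_home_incremental_frac: float = 0.05
    nursing_home_incremental_years: float = 2.0
    nursing_home_copay_frac: float = 0.15  # midpoint of the 10-20% income-dependent band
    food_service_frac: float = 0.12
    food_deliveries_per_year: float = 365.0
    device_uptake: tuple = (1.0,) * 8  # per-device uptake per hip fracture
    device_regional_frac: float = 0.25  # regions fund 25% of devices, municipalities 75%
    # continuing use
    gp_incremental_frac: float = 0.157
    personal_care_incremental_frac: float = 0.166
    personal_care_hours_per_week: float = 3.7
    pharma_reimbursement_frac: float = 0.75
    persistence: tuple = (0.7, 0.49, 0.343, 0.2401, 0.16807)  # per-year treatment persistence
    well_continuing: bool = False  # attach pharma/GP continuing costs to well
    # productivity
    los_wrist_days: float = 1.0
    los_vertebral_days: float = 4.0
    hip_absence_working_days: float = 65.0  # "3 months" = 13 weeks x 5 working days
    retirement_age: int = 65
    participation_rate: float = 0.75
    work_days_per_year: float = 220.0

    def __post_init__(self) -> None:
        split = (
            self.vertebral_hospital_frac
            + self.vertebral_gp_frac
            + self.vertebral_undiagnosed_frac
        )
        if abs(split - 1.0) > 1e-9:
            raise ValueError(f"vertebral pathway split must sum to 1, got {split}")
        for f in dataclasses.fields(self):
            if f.name.endswith("_frac"):
                v = getattr(self, f.name)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{f.name} must lie in [0, 1], got {v}")

    def hip_fixation_frac(self, gender: str) -> float:
        return self.hip_fixation_frac_male if gender == "male" else self.hip_fixation_frac_female

    @property
    def persistence_weight(self) -> float:
        """Mean on-treatment fraction over the persistence horizon."""
        if not self.persistence:
            return 0.0
        return float(np.mean(self.persistence))


# --- event costs -----------------------------------------------------------


def wrist_event_cost(gender: str, unit: UnitCostTable, path: PathwayParams) -> PayerLedger:
    """One-off cost of an incident wrist fracture.

    The operated share receives orthopaedic care, the rest emergency-room
    care; every diagnosed wrist fracture gets one DXA scan (regional).
    A quarter are referred to physiotherapy, priced at the municipal
    rehabilitation hourly rate.
    """
    regional = (
        path.wrist_surgery_frac * unit.wrist_orthopaedic
        + (1.0 - path.wrist_surgery_frac) * unit.emergency_room
        + unit.dxa_scan
    )
    municipal = path.wrist_physio_frac * path.physio_sessions * unit.rehab_hourly
    return PayerLedger(regional=regional, municipal=municipal)


def vertebral_event_cost(gender: str, unit: UnitCostTable, path: PathwayParams) -> PayerLedger:
    """One-off cost of an incident vertebral fracture.

    Only the diagnosed half generates cost: the hospital-treated tenth
    is costed at a mix of vertebroplasty and conservative medical
    treatment plus DXA; the GP-treated 40% at the GP fee plus
    pain-relief medication charged fully to the patient; the
    undiagnosed half costs nothing.
    """
    diagnosed = path.vertebral_hospital_frac + path.vertebral_gp_frac
    regional = path.vertebral_hospital_frac * (
        path.vertebral_pvp_mix * unit.vertebral_pvp
        + (1.0 - path.vertebral_pvp_mix) * unit.vertebral_medical
    ) + diagnosed * unit.dxa_scan
    general_practice = path.vertebral_gp_frac * unit.gp_annual
    patient = path.vertebral_gp_frac * unit.pain_relief_annual
    return PayerLedger(regional=regional, general_practice=general_practice, patient=patient)


def hip_event_cost(gender: str, unit: UnitCostTable, path: PathwayParams) -> PayerLedger:
    """One-off cost of an incident hip fracture (first or second).

    Regional: the surgical mix (gender-specific internal-fixation share
    split between the two fixation tariffs, remainder alloplastic), DXA,
    and a quarter of the assistive-device bundle.  Municipal: standard
    rehabilitation, respite care, the incremental nursing-home stay net
    of co-payment, food service, and three quarters of the devices.
    Patient: respite and nursing-home co-payments and food co-payments.
    """
    fix = path.hip_fixation_frac(gender)
    surgery = fix * (
        path.fixation_tariff_mix * unit.hip_internal_fixation
        + (1.0 - path.fixation_tariff_mix) * unit.hip_pertrochanteric_fixation
    ) + (1.0 - fix) * unit.hip_alloplastic
    devices = float(np.dot(np.asarray(path.device_uptake), unit.device_prices()))

    regional = surgery + unit.dxa_scan + path.device_regional_frac * devices

    rehab = (
        path.standard_rehab_frac * path.rehab_hours_per_week * path.rehab_weeks * unit.rehab_hourly
        + (1.0 - path.standard_rehab_frac)
        * path.rehab_hours_per_week
        * path.rehab_weeks
        * unit.rehab_home_hourly
    )
    respite_m = path.respite_frac * path.respite_days * unit.respite_daily
    nursing_total = (
        path.nursing_home_incremental_frac
        * path.nursing_home_incremental_years
        * unit.nursing_home_yearly
    )
    food_m = path.food_service_frac * path.food_deliveries_per_year * unit.food_delivery_municipal
    municipal = (
        rehab
        + respite_m
        + nursing_total * (1.0 - path.nursing_home_copay_frac)
        + food_m
        + (1.0 - path.device_regional_frac) * devices
    )

    respite_p = path.respite_frac * path.respite_days * unit.respite_copay_daily
    nursing_p = nursing_total * path.nursing_home_copay_frac
    nh_food_p = (
        path.nursing_home_incremental_frac
        * path.nursing_home_incremental_years
        * 365.0
        * unit.food_delivery_copay
    )
    food_p = path.food_service_frac * path.food_deliveries_per_year * unit.food_delivery_copay
    patient = respite_p + nursing_p + nh_food_p + food_p

    return PayerLedger(regional=regional, municipal=municipal, patient=patient)


_EVENT_COST_FN = {
    State.WRIST: wrist_event_cost,
    State.VERTEBRAL: vertebral_event_cost,
    State.FIRST_HIP: hip_event_cost,
    State.SECOND_HIP: hip_event_cost,
}


def annual_continuing_cost(
    state: State, gender: str, unit: UnitCostTable, path: PathwayParams
) -> PayerLedger:
    """Continuing cost per year of residence in ``state``.

    Post-fracture states accrue anti-osteoporotic pharmaceutical cost
    (weighted by the mean treatment persistence, split 75% regional /
    25% patient) and the incremental GP contact; post-hip states
    additionally accrue incremental personal care (municipal).  The
    well state accrues the pharma/GP components only when
    ``path.well_continuing`` is set; all other states cost nothing.
    """
    if state is State.WELL and not path.well_continuing:
        return PayerLedger()
    if state not in POST_STATES and state is not State.WELL:
        return PayerLedger()

    pharma = unit.pharma_annual(gender) * path.persistence_weight
    regional = path.pharma_reimbursement_frac * pharma
    patient = (1.0 - path.pharma_reimbursement_frac) * pharma
    general_practice = path.gp_incremental_frac * unit.gp_annual
    municipal = 0.0
    if state in (State.POST_FIRST_HIP, State.POST_SECOND_HIP):
        municipal = (
            path.personal_care_incremental_frac
            * path.personal_care_hours_per_week
            * 52.0
            * unit.personal_care_hourly
        )
    return PayerLedger(
        regional=regional,
        general_practice=general_practice,
        municipal=municipal,
        patient=patient,
    )


def productivity_cost(
    event: str,
    gender: str,
    age: int,
    unit: UnitCostTable,
    path: PathwayParams,
    discount: DiscountSpec = DiscountSpec(),
) -> float:
    """Human-capital productivity loss for one event at ``age`` (EUR).

    ``event`` is ``'wrist'``, ``'vertebral'`` or ``'hip'`` (absence
    days times the daily wage) or ``'death'`` (the discounted stream of
    annual wages from ``age`` to retirement).  Both are weighted by the
    labour-force participation rate, and both are zero at or beyond
    retirement age.
    """
    if age >= path.retirement_age:
        return 0.0
    if event == "death":
        total = 0.0
        for t in range(age, path.retirement_age):
            annual = unit.wage(gender, t) * path.work_days_per_year
            total += annual * discount_factor(discount, t - age)
        return total * path.participation_rate
    days = {
        "wrist": path.los_wrist_days,
        "vertebral": path.los_vertebral_days,
        "hip": path.hip_absence_working_days,
    }.get(event)
    if days is None:
        raise ValueError(f"unknown productivity event {event!r}")
    wage = unit.wage(gender, age)
    if wage < 0:
        raise ValueError("negative wage")
    return days * wage * path.participation_rate


# --- the full profile ------------------------------------------------------


@dataclass
class StateCostProfile:
    """Per-age, per-state cost ledgers ready for trajectory costing.

    ``event[a, s, p]`` is the one-off cost billed to payer ``p`` when a
    person enters state ``s`` at age index ``a``; ``continuing[a, s, p]``
    the annual cost of residing there.  Death costs nothing.
    """

    gender: str
    event: np.ndarray  # (N_AGES, 10, 5)
    continuing: np.ndarray  # (N_AGES, 10, 5)

    def event_ledger(self, age: int, state: State) -> PayerLedger:
        vals = self.event[age - AGE_MIN, int(state)]
        return PayerLedger(**dict(zip(PAYERS, vals)))

    def continuing_ledger(self, age: int, state: State) -> PayerLedger:
        vals = self.continuing[age - AGE_MIN, int(state)]
        return PayerLedger(**dict(zip(PAYERS, vals)))


def build_state_cost_profile(
    gender: str,
    unit: UnitCostTable,
    path: PathwayParams,
    epi=None,
    discount: DiscountSpec = DiscountSpec(),
) -> StateCostProfile:
    """Assemble the full event/continuing cost profile for one gender.

    Fracture events carry their direct event cost plus the sick-day
    wage loss and, when epidemiology inputs are supplied, the expected
    premature-death wage loss: the excess probability of dying in the
    fracture year (mortality under the state's relative risk minus
    background) times the discounted wage stream to retirement.
    """
    from .transitions import rate_to_probability  # local import avoids a cycle

    event = np.zeros((N_AGES, N_STATES, len(PAYERS)))
    continuing = np.zeros((N_AGES, N_STATES, len(PAYERS)))
    gi = 0 if gender == "male" else 1

    for s in FRACTURE_STATES:
        base = _EVENT_COST_FN[s](gender, unit, path).as_array()
        ftype = {State.WRIST: "wrist", State.VERTEBRAL: "vertebral"}.get(s, "hip")
        for ai, age in enumerate(AGES):
            ledger = base.copy()
            prod = productivity_cost(ftype, gender, age, unit, path, discount)
            if epi is not None:
                context = MORTALITY_CONTEXT_OF[s]
                p_rr = rate_to_probability(
                    epi.mortality[gi, ai] * epi.rr_death[int(context)]
                )
                p_bg = rate_to_probability(epi.mortality[gi, ai])
                excess = max(p_rr - p_bg, 0.0)
                prod += excess * productivity_cost("death", gender, age, unit, path, discount)
            ledger[PAYERS.index("productivity")] += prod
            event[ai, int(s)] = ledger

    for s in POST_STATES + (State.WELL,):
        cont = annual_continuing_cost(s, gender, unit, path).as_array()
        continuing[:, int(s)] = cont

    return StateCostProfile(gender=gender, event=event, continuing=continuing)
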