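"""End-to-end model runs: inputs + configuration -> result bundle."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig
from .costs import build_state_cost_profile
from .markov import N_STATES, run_cohort, validate_transition_table
from .pipeline import (
    CostDecomposition,
    NationalBurden,
    annual_cost_series,
    lifetime_cost_by_payer,
    lifetime_cost_by_state,
    most_costly_age,
    national_total,
)
from .states import AGE_MAX, AGE_MIN, GENDERS, HIP_STATES, State
from .transitions import EpidemiologyInputs, build_table

__all__ = ["GenderResult", "AnalysisResult", "run_analysis"]


@dataclass
class GenderResult:
    """Per-gender results of one full model run."""

    gender: str
    by_state: CostDecomposition
    by_payer: CostDecomposition
    annual_costs: pd.Series  # undiscounted per-alive-person cost by age
    most_costly_age: int

    @property
    def lifetime_cost(self) -> float:
        return self.by_state.total

    def hip_state_share(self) -> float:
        """Percentage of lifetime cost in the four hip-related states."""
        if self.by_state.shares is None:
            return 0.0
        return sum(self.by_state.shares[s.label] for s in HIP_STATES)


@dataclass
class AnalysisResult:
    genders: dict[str, GenderResult]
    national: NationalBurden | None

    def lifetime_costs(self) -> dict[str, float]:
        return {g: r.lifetime_cost for g, r in self.genders.items()}


def run_analysis(
    config: ModelConfig,
    epi: EpidemiologyInputs,
    demography: pd.DataFrame | None = None,
    start_age: int = AGE_MIN,
    horizon_age: int = AGE_MAX,
) -> AnalysisResult:
    """Run the full costing pipeline for both genders.

    Builds and validates the transition table from ``epi``, follows a
    unit cohort starting well at ``start_age``, costs the trajectory,
    and (when a demography table is given) scales per-person annual
    costs to the national at-risk population.
    """
    table = build_table(epi, rr_scale=config.rr_scale)
    violations = validate_transition_table(table)
    if violations:
        raise ValueError(
            f"built transition table is invalid ({len(violations)} violations; "
            f"first: {violations[0]})"
        )

    results: dict[str, GenderResult] = {}
    annual: dict[str, pd.Series] = {}
    for gender in GENDERS:
        profile = build_state_cost_profile(
            gender, config.unit_costs, config.pathways, epi=epi, discount=config.discount
        )
        initial = np.zeros(N_STATES)
        initial[State.WELL] = 1.0
        trajectory = run_cohort(initial, start_age, gender, table, horizon_age)
        by_state = lifetime_cost_by_state(trajectory, profile, config.discount)
        by_payer = lifetime_cost_by_payer(trajectory, profile, config.discount)
        series = annual_cost_series(trajectory, profile)
        results[gender] = GenderResult(
            gender=gender,
            by_state=by_state,
            by_payer=by_payer,
            annual_costs=series,
            most_costly_age=most_costly_age(series),
        )
        annual[gender] = series

    national = None
    if demography is not None:
        national = national_total(annual, demography, config.at_risk_frac)
    return AnalysisResult(genders=results, national=national)
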