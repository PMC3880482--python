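"""Orchestration: lifetime cost decompositions and national aggregation.

A run couples a cohort trajectory (who is where, when) with a cost
profile (what each state costs, for whom) to produce the three result
products: discounted incremental lifetime cost per person decomposed
by health state, the same total decomposed by payer, and the national
annual burden by age band and gender obtained by weighting per-person
annual cost with the at-risk population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .costs import PAYERS, StateCostProfile
from .markov import CohortTrajectory, DiscountSpec, discount_factor
from .states import AGE_BANDS, AGE_MIN, State, age_band_label

__all__ = [
    "CostDecomposition",
    "NationalBurden",
    "aggregate_decomposition",
    "cost_cube",
    "lifetime_cost_by_state",
    "lifetime_cost_by_payer",
    "annual_cost_series",
    "most_costly_age",
    "national_total",
]

#: published at-risk fractions of the 50+ population, by gender
AT_RISK_FRAC = {"male": 0.177, "female": 0.408}
#: published at-risk cohort sizes the demography calibrates to
AT_RISK_COHORT = {"male": 149_466, "female": 388_474}


@dataclass
class CostDecomposition:
    """Labelled cost components with their total and percentage shares."""

    entries: dict[str, float]
    total: float
    shares: dict[str, float] | None  # None when the total is zero

    def rounded(self, ndigits: int = 2) -> "CostDecomposition":
        entries = {k: round(v, ndigits) for k, v in self.entries.items()}
        shares = (
            None if self.shares is None else {k: round(v, ndigits) for k, v in self.shares.items()}
        )
        return CostDecomposition(entries=entries, total=round(self.total, ndigits), shares=shares)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"label": k, "cost": v, "share_pct": None if self.shares is None else self.shares[k]}
            for k, v in self.entries.items()
        ]
        rows.append({"label": "total", "cost": self.total,
                     "share_pct": None if self.shares is None else 100.0})
        return pd.DataFrame(rows)


def aggregate_decomposition(entries: Mapping[str, float]) -> CostDecomposition:
    """Sum labelled cost entries and compute percentage shares.

    Raises on negative or non-finite entries.  An empty or all-zero
    input yields total 0 with ``shares=None``.
    """
    clean: dict[str, float] = {}
    for label, value in entries.items():
        value = float(value)
        if not np.isfinite(value):
            raise ValueError(f"non-finite entry for {label!r}")
        if value < 0:
            raise ValueError(f"negative entry for {label!r}: {value}")
        clean[label] = value
    total = float(sum(clean.values()))
    if total == 0.0:
        return CostDecomposition(entries=clean, total=0.0, shares=None)
    shares = {k: 100.0 * v / total for k, v in clean.items()}
    return CostDecomposition(entries=clean, total=total, shares=shares)


def cost_cube(
    trajectory: CohortTrajectory,
    profile: StateCostProfile,
    discount: DiscountSpec = DiscountSpec(),
    per_person: bool = True,
) -> np.ndarray:
    """Discounted cost per (cycle, state, payer) for a costed run.

    Continuing costs accrue on the occupancy of each cycle; event costs
    on the tracker inflow of the cycle of entry.  With half-cycle
    correction enabled on ``discount``, continuing costs are discounted
    at ``cycle + 0.5`` (membership counted mid-cycle) while event costs
    stay at the entry cycle.
    """
    if trajectory.gender != profile.gender:
        raise ValueError(
            f"gender mismatch: trajectory is {trajectory.gender}, profile is {profile.gender}"
        )
    n = trajectory.n_cycles
    ages = trajectory.ages
    age_idx = ages - AGE_MIN
    cont = profile.continuing[age_idx]  # (n, 10, 5)
    evt = profile.event[age_idx]
    cycles = np.arange(n, dtype=float)
    d_event = (1.0 + discount.annual_rate) ** (-cycles)
    d_cont = (
        (1.0 + discount.annual_rate) ** (-(cycles + 0.5)) if discount.half_cycle else d_event
    )
    cube = (
        trajectory.occupancy[:, :, None] * cont * d_cont[:, None, None]
        + trajectory.trackers[:, :, None] * evt * d_event[:, None, None]
    )
    if per_person:
        size = trajectory.cohort_size
        if size <= 0:
            raise ValueError("cohort size must be positive for per-person costs")
        cube = cube / size
    return cube


def lifetime_cost_by_state(
    trajectory: CohortTrajectory,
    profile: StateCostProfile,
    discount: DiscountSpec = DiscountSpec(),
    per_person: bool = True,
) -> CostDecomposition:
    """Discounted lifetime cost decomposed over the ten health states."""
    cube = cost_cube(trajectory, profile, discount, per_person)
    by_state = cube.sum(axis=(0, 2))
    return aggregate_decomposition({s.label: by_state[int(s)] for s in State})


def lifetime_cost_by_payer(
    trajectory: CohortTrajectory,
    profile: StateCostProfile,
    discount: DiscountSpec = DiscountSpec(),
    per_person: bool = True,
) -> CostDecomposition:
    """The same lifetime total decomposed over the five payers."""
    cube = cost_cube(trajectory, profile, discount, per_person)
    by_payer = cube.sum(axis=(0, 1))
    return aggregate_decomposition(dict(zip(PAYERS, by_payer)))


def annual_cost_series(
    trajectory: CohortTrajectory,
    profile: StateCostProfile,
    per_alive_person: bool = True,
) -> pd.Series:
    """Undiscounted cost accrued at each model age.

    By default normalised by the persons alive at that age, giving the
    per-person annual cost used for national aggregation; ages where
    nobody is alive yield 0.
    """
    cube = cost_cube(
        trajectory, profile, DiscountSpec(annual_rate=0.0), per_person=False
    )
    totals = cube.sum(axis=(1, 2))
    if per_alive_person:
        alive = trajectory.occupancy[:, : int(State.DEATH)].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            totals = np.where(alive > 0, totals / np.where(alive > 0, alive, 1.0), 0.0)
    return pd.Series(totals, index=trajectory.ages, name="annual_cost")


def most_costly_age(annual_costs: pd.Series) -> int:
    """Age with the highest annual cost; ties resolve to the youngest age."""
    if len(annual_costs) == 0:
        raise ValueError("empty cost series")
    s = annual_costs.sort_index()
    return int(s.index[np.argmax(s.to_numpy())])


@dataclass
class NationalBurden:
    """Annual national cost by gender and five-year age band (EUR/year)."""

    cost: pd.DataFrame  # columns: gender, age_band, at_risk, cost
    gender_totals: dict[str, float]
    grand_total: float
    mode: str = "annual"


def national_total(
    annual_costs: Mapping[str, pd.Series],
    demography: pd.DataFrame,
    at_risk_frac: Mapping[str, float] | None = None,
    mode: str = "annual",
    lifetime_costs: Mapping[str, float] | None = None,
) -> NationalBurden:
    """Scale modelled per-person costs to the national at-risk population.

    In the default ``'annual'`` mode the cost of a band is the at-risk
    population of that band times the mean modelled per-person annual
    cost over the band's ages; in ``'lifetime'`` mode the per-gender
    burden is simply the at-risk cohort times the per-person lifetime
    cost (an alternative reading of national aggregation, reported for
    comparison only).

    ``demography`` needs columns gender, age_band, population and,
    optionally, at_risk; absent the latter, at-risk counts are
    ``population * at_risk_frac[gender]``.
    """
    required = {"gender", "age_band", "population"}
    if missing := required - set(demography.columns):
        raise ValueError(f"demography missing columns: {sorted(missing)}")
    demo = demography.copy()
    if "at_risk" not in demo.columns:
        if at_risk_frac is None:
            at_risk_frac = AT_RISK_FRAC
        demo["at_risk"] = demo.apply(
            lambda r: r["population"] * at_risk_frac[r["gender"]], axis=1
        )

    rows = []
    gender_totals: dict[str, float] = {}
    for gender, series in annual_costs.items():
        sub = demo[demo["gender"] == gender]
        if mode == "lifetime":
            if lifetime_costs is None:
                raise ValueError("lifetime mode needs lifetime_costs")
            total = float(sub["at_risk"].sum()) * lifetime_costs[gender]
            gender_totals[gender] = total
            rows.append({"gender": gender, "age_band": "all", "at_risk": float(sub["at_risk"].sum()), "cost": total})
            continue
        band_cost = series.groupby(series.index.map(age_band_label)).mean()
        g_total = 0.0
        for _, r in sub.iterrows():
            band = r["age_band"]
            if band not in band_cost.index:
                raise ValueError(f"no modelled cost for age band {band!r} ({gender})")
            c = float(r["at_risk"]) * float(band_cost[band])
            rows.append({"gender": gender, "age_band": band, "at_risk": float(r["at_risk"]), "cost": c})
            g_total += c
        gender_totals[gender] = g_total
    frame = pd.DataFrame(rows)
    return NationalBurden(
        cost=frame,
        gender_totals=gender_totals,
        grand_total=float(sum(gender_totals.values())),
        mode=mode,
    )
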