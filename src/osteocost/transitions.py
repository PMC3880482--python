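"""Build transition tables from epidemiological primitives.

Inputs are the quantities a fracture registry and the literature
provide: age/gender incidence rates per fracture type (events per
person-year), background all-cause mortality rates, and post-fracture
relative risks of re-fracture and of death.  Rates are converted to
one-cycle probabilities with the standard exponential transform
``p = 1 - exp(-rate * t)``, and relative risks are applied on the
hazard scale (``1 - (1 - p)^rr``), which keeps results inside [0, 1)
for any positive risk ratio; a probability-scale option (``p * rr``)
is provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import N_STATES, TransitionTable
from .states import (
    AGE_MIN,
    AGES,
    FRACTURE_TYPES,
    GENDERS,
    MORTALITY_CONTEXT_OF,
    N_AGES,
    RESIDUAL_OF,
    State,
    allowed_fracture_destinations,
    default_mask,
)

__all__ = [
    "EpidemiologyInputs",
    "rate_to_probability",
    "apply_relative_risk",
    "build_table",
]

_FTYPE_IDX = {t: i for i, t in enumerate(FRACTURE_TYPES)}
_GENDER_IDX = {g: i for i, g in enumerate(GENDERS)}


@dataclass
class EpidemiologyInputs:
    """Rates and relative risks driving the transition table.

    Attributes
    ----------
    incidence
        ``(2, 50, 3)`` events per person-year, indexed by
        (gender, age-50, fracture type in ``FRACTURE_TYPES`` order).
    mortality
        ``(2, 50)`` background all-cause death rate per person-year.
    rr_refracture
        ``(10, 3)`` relative risk of a new fracture of each type given
        the current state (1.0 for well; acute states share their post
        state's value).
    rr_death
        ``(10,)`` relative mortality risk per state (1.0 for well).
    """

    incidence: np.ndarray
    mortality: np.ndarray
    rr_refracture: np.ndarray = field(
        default_factory=lambda: np.ones((N_STATES, len(FRACTURE_TYPES)))
    )
    rr_death: np.ndarray = field(default_factory=lambda: np.ones(N_STATES))

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=float)
        self.mortality = np.asarray(self.mortality, dtype=float)
        self.rr_refracture = np.asarray(self.rr_refracture, dtype=float)
        self.rr_death = np.asarray(self.rr_death, dtype=float)
        if self.incidence.shape != (len(GENDERS), N_AGES, len(FRACTURE_TYPES)):
            raise ValueError(
                f"incidence must have shape (2, {N_AGES}, {len(FRACTURE_TYPES)})"
            )
        if self.mortality.shape != (len(GENDERS), N_AGES):
            raise ValueError(f"mortality must have shape (2, {N_AGES})")
        if np.any(self.incidence < 0) or np.any(self.mortality < 0):
            raise ValueError("rates must be nonnegative")
        if np.any(self.rr_refracture <= 0) or np.any(self.rr_death <= 0):
            raise ValueError("relative risks must be positive")

    # -- serialisation ------------------------------------------------------

    def to_files(self, incidence_path, mortality_path, rr_path) -> None:
        """Write the three long-format CSV files consumed by :meth:`from_files`."""
        inc_rows = [
            (g, age, t, self.incidence[gi, ai, ti])
            for gi, g in enumerate(GENDERS)
            for ai, age in enumerate(AGES)
            for ti, t in enumerate(FRACTURE_TYPES)
        ]
        pd.DataFrame(inc_rows, columns=["gender", "age", "fracture_type", "rate"]).to_csv(
            incidence_path, index=False, float_format="%.12g"
        )
        mort_rows = [
            (g, age, self.mortality[gi, ai])
            for gi, g in enumerate(GENDERS)
            for ai, age in enumerate(AGES)
        ]
        pd.DataFrame(mort_rows, columns=["gender", "age", "rate"]).to_csv(
            mortality_path, index=False, float_format="%.12g"
        )
        rr_rows = []
        for s in State:
            if s is State.DEATH:
                continue
            for ti, t in enumerate(FRACTURE_TYPES):
                rr_rows.append(("refracture", s.label, t, self.rr_refracture[int(s), ti]))
            rr_rows.append(("death", s.label, "", self.rr_death[int(s)]))
        pd.DataFrame(rr_rows, columns=["rr_type", "state", "fracture_type", "value"]).to_csv(
            rr_path, index=False, float_format="%.12g"
        )

    @classmethod
    def from_files(cls, incidence_path, mortality_path, rr_path) -> "EpidemiologyInputs":
        inc = pd.read_csv(incidence_path)
        mort = pd.read_csv(mortality_path)
        rr = pd.read_csv(rr_path, keep_default_na=False)
        incidence = np.zeros((len(GENDERS), N_AGES, len(FRACTURE_TYPES)))
        incidence[
            inc["gender"].map(_GENDER_IDX),
            inc["age"].astype(int) - AGE_MIN,
            inc["fracture_type"].map(_FTYPE_IDX),
        ] = inc["rate"].astype(float)
        mortality = np.zeros((len(GENDERS), N_AGES))
        mortality[
            mort["gender"].map(_GENDER_IDX), mort["age"].astype(int) - AGE_MIN
        ] = mort["rate"].astype(float)
        rr_refracture = np.ones((N_STATES, len(FRACTURE_TYPES)))
        rr_death = np.ones(N_STATES)
        for _, row in rr.iterrows():
            s = int(State.from_label(row["state"]))
            if row["rr_type"] == "refracture":
                rr_refracture[s, _FTYPE_IDX[row["fracture_type"]]] = float(row["value"])
            elif row["rr_type"] == "death":
                rr_death[s] = float(row["value"])
            else:
                raise ValueError(f"unknown rr_type {row['rr_type']!r}")
        return cls(incidence, mortality, rr_refracture, rr_death)


def rate_to_probability(rate, duration: float = 1.0):
    """Convert an event rate (per person-year) to a per-cycle probability.

    ``p = 1 - exp(-rate * duration)``: monotone in the rate and bounded
    in [0, 1).  Accepts scalars or arrays.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be nonnegative")
    out = -np.expm1(-rate * duration)
    return float(out) if out.ndim == 0 else out


def apply_relative_risk(base_prob, rr: float, scale: str = "hazard"):
    """Apply a relative risk to a baseline probability.

    ``scale='hazard'`` (default) computes ``1 - (1 - p)^rr``, i.e. the
    risk ratio multiplies the underlying hazard; ``scale='probability'``
    computes ``min(p * rr, 1)``.
    """
    base_prob = np.asarray(base_prob, dtype=float)
    if rr <= 0:
        raise ValueError("relative risk must be positive")
    if np.any(base_prob < 0) or np.any(base_prob > 1):
        raise ValueError("base probability must lie in [0, 1]")
    if np.any((base_prob == 1.0) & (rr != 1.0)):
        raise ValueError("cannot rescale a probability of exactly 1")
    if scale == "hazard":
        out = 1.0 - (1.0 - base_prob) ** rr
    elif scale == "probability":
        out = np.minimum(base_prob * rr, 1.0)
    else:
        raise ValueError(f"unknown scale {scale!r}; use 'hazard' or 'probability'")
    return float(out) if out.ndim == 0 else out


def build_table(
    epi: EpidemiologyInputs,
    mask: np.ndarray | None = None,
    rr_scale: str = "hazard",
) -> TransitionTable:
    """Assemble the full transition table from epidemiological inputs.

    For every (gender, age, from-state) row: the death probability is
    the converted background mortality under the state's mortality
    relative risk; each fracture destination permitted by ``mask`` gets
    the converted incidence under the state's re-fracture relative
    risk; the remaining mass goes to the residual destination (self for
    well and post states, the matching post state for acute states).
    If death plus fracture probabilities exceed 1 the fracture
    probabilities are scaled down proportionally and a warning is
    issued.
    """
    if mask is None:
        mask = default_mask()
    table = TransitionTable.zeros()
    repaired: list[tuple[str, int, str]] = []
    for gi, gender in enumerate(GENDERS):
        for ai, age in enumerate(AGES):
            m = table.p[gi, ai]
            m[State.DEATH, State.DEATH] = 1.0
            for s in State:
                if s is State.DEATH:
                    continue
                row = np.zeros(N_STATES)
                context = MORTALITY_CONTEXT_OF[s]
                p_death = rate_to_probability(
                    epi.mortality[gi, ai] * epi.rr_death[int(context)]
                )
                frac_total = 0.0
                for dest in allowed_fracture_destinations(s):
                    if not mask[int(s), int(dest)]:
                        continue
                    ftype = _FTYPE_IDX[
                        {"first_hip": "hip", "second_hip": "hip"}.get(dest.label, dest.label)
                    ]
                    base = rate_to_probability(epi.incidence[gi, ai, ftype])
                    rr = epi.rr_refracture[int(context), ftype]
                    p = apply_relative_risk(base, rr, scale=rr_scale)
                    row[int(dest)] = p
                    frac_total += p
                if p_death + frac_total > 1.0:
                    scale_fix = (1.0 - p_death) / frac_total
                    row *= scale_fix
                    frac_total *= scale_fix
                    repaired.append((gender, age, s.label))
                row[int(State.DEATH)] = p_death
                residual = 1.0 - p_death - frac_total
                row[int(RESIDUAL_OF[s])] += max(residual, 0.0)
                m[int(s)] = row
    if repaired:
        warnings.warn(
            f"fracture probabilities rescaled to fit unit row sum in {len(repaired)} rows "
            f"(first: {repaired[0]})",
            stacklevel=2,
        )
    return table
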