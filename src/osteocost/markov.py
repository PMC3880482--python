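"""Cohort Markov engine: transition tables, cycle stepping and discounting.

The engine propagates a population vector over the ten health states
through age- and gender-specific row-stochastic matrices, one matrix per
model year.  Alongside occupancy it records *tracker* counts — the
inflow into each acute fracture state per cycle — which carry the
one-off fracture event costs and double as a debugging handle: summed
over cycles they are the modelled fracture counts that can be compared
against registry incidence.

A per-individual microsimulation of the same chain is provided as an
independent stochastic oracle for validating the deterministic cohort
arithmetic; it is intended for tests, not production runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .states import (
    AGE_MAX,
    AGE_MIN,
    AGES,
    FRACTURE_STATES,
    GENDERS,
    N_AGES,
    State,
    default_mask,
)

__all__ = [
    "TransitionTable",
    "CohortTrajectory",
    "DiscountSpec",
    "Violation",
    "validate_transition_table",
    "step_cohort",
    "run_cohort",
    "discount_factor",
    "microsim_oracle",
    "MicrosimResult",
]

N_STATES = len(State)

_GENDER_IDX = {g: i for i, g in enumerate(GENDERS)}

ROW_SUM_TOL = 1e-9


def _gender_index(gender: str) -> int:
    try:
        return _GENDER_IDX[gender]
    except KeyError:
        raise ValueError(f"unknown gender {gender!r}; expected one of {GENDERS}") from None


@dataclass
class TransitionTable:
    """Age- and gender-indexed one-cycle transition probabilities.

    Parameters
    ----------
    p
        Array of shape ``(2, 50, 10, 10)`` indexed by
        ``(gender, age - 50, from_state, to_state)``; each
        ``(from_state, to_state)`` slice is a row-stochastic matrix.
    """

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        expected = (len(GENDERS), N_AGES, N_STATES, N_STATES)
        if self.p.shape != expected:
            raise ValueError(f"transition array must have shape {expected}, got {self.p.shape}")

    @classmethod
    def zeros(cls) -> "TransitionTable":
        return cls(np.zeros((len(GENDERS), N_AGES, N_STATES, N_STATES)))

    def matrix(self, gender: str, age: int) -> np.ndarray:
        """The (10, 10) matrix applying at ``(gender, age)``."""
        if not AGE_MIN <= age <= AGE_MAX:
            raise ValueError(f"age {age} outside model range [{AGE_MIN}, {AGE_MAX}]")
        return self.p[_gender_index(gender), age - AGE_MIN]

    # -- serialisation ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns gender, age, from_state, to_state, probability."""
        g, a, i, j = np.nonzero(np.ones_like(self.p))
        frame = pd.DataFrame(
            {
                "gender": np.array(GENDERS)[g],
                "age": a + AGE_MIN,
                "from_state": [State(k).label for k in i],
                "to_state": [State(k).label for k in j],
                "probability": self.p[g, a, i, j],
            }
        )
        return frame[frame["probability"] != 0.0].reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TransitionTable":
        required = {"gender", "age", "from_state", "to_state", "probability"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"transition frame missing columns: {sorted(missing)}")
        table = cls.zeros()
        g = frame["gender"].map(_GENDER_IDX)
        if g.isna().any():
            bad = frame.loc[g.isna(), "gender"].unique()
            raise ValueError(f"unknown gender values: {list(bad)}")
        a = frame["age"].astype(int) - AGE_MIN
        i = frame["from_state"].map(lambda s: int(State.from_label(s)))
        j = frame["to_state"].map(lambda s: int(State.from_label(s)))
        table.p[g, a, i, j] = frame["probability"].astype(float)
        return table

    def to_csv(self, path) -> None:
        # 12 significant digits keeps the round trip bit-stable at that precision
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "TransitionTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class Violation:
    """One failed transition-table invariant, locating the offending row."""

    rule: str
    gender: str | None
    age: int | None
    from_state: str | None
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"({self.gender}, {self.age}, {self.from_state})"
        return f"{self.rule} at {where}: {self.detail}"


def validate_transition_table(
    table: TransitionTable,
    mask: np.ndarray | None = None,
    row_sum_tol: float = ROW_SUM_TOL,
) -> list[Violation]:
    """Check every row of ``table`` against the model invariants.

    Returns an empty list iff the table is valid: probabilities in
    [0, 1], rows summing to 1 within ``row_sum_tol``, death absorbing,
    and all transitions outside ``mask`` exactly zero.
    """
    if mask is None:
        mask = default_mask()
    violations: list[Violation] = []
    for gi, gender in enumerate(GENDERS):
        for ai, age in enumerate(AGES):
            m = table.p[gi, ai]
            if not np.any(m):
                violations.append(
                    Violation("missing-slice", gender, age, None, "all-zero transition matrix")
                )
                continue
            for s in State:
                row = m[int(s)]
                if np.any(row < 0) or np.any(row > 1):
                    violations.append(
                        Violation(
                            "range", gender, age, s.label,
                            f"entries outside [0, 1]: {row[(row < 0) | (row > 1)]}",
                        )
                    )
                total = row.sum()
                if abs(total - 1.0) > row_sum_tol:
                    violations.append(
                        Violation("row-sum", gender, age, s.label, f"row sums to {total!r}")
                    )
                off_mask = row[~mask[int(s)]]
                if np.any(off_mask != 0.0):
                    bad = [
                        State(j).label
                        for j in np.nonzero(~mask[int(s)])[0]
                        if row[j] != 0.0
                    ]
                    violations.append(
                        Violation(
                            "mask", gender, age, s.label,
                            f"nonzero probability on masked transitions to {bad}",
                        )
                    )
            if m[State.DEATH, State.DEATH] != 1.0:
                violations.append(
                    Violation(
                        "absorbing-death", gender, age, State.DEATH.label,
                        f"death self-transition is {m[State.DEATH, State.DEATH]!r}, not 1",
                    )
                )
    return violations


def step_cohort(
    occupancy: np.ndarray, matrix: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Advance a cohort one cycle through a single transition matrix.

    Parameters
    ----------
    occupancy
        Nonnegative person counts per state, shape (10,).
    matrix
        Row-stochastic (10, 10) matrix for the cohort's current
        gender/age.

    Returns
    -------
    next_occupancy, trackers
        The propagated occupancy and, for each state, the inflow from
        *other* states that cycle (nonzero only for fracture states in
        a masked table; returned for all states for generality).
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.shape != (N_STATES,):
        raise ValueError(f"occupancy must have shape ({N_STATES},)")
    if np.any(occupancy < 0):
        raise ValueError("occupancy must be nonnegative")
    nxt = occupancy @ matrix
    inflow = nxt - occupancy * np.diag(matrix)  # inflow from other states
    return nxt, inflow


@dataclass
class CohortTrajectory:
    """Per-cycle state occupancy and incident fracture counts.

    ``occupancy[c]`` is the population vector at age ``start_age + c``;
    ``trackers[c]`` the inflow into each state during the cycle ending
    at that age (``trackers[0]`` is zero: the initial distribution is
    given, not simulated).
    """

    gender: str
    start_age: int
    occupancy: np.ndarray  # (n_cycles, 10)
    trackers: np.ndarray  # (n_cycles, 10)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    @property
    def cohort_size(self) -> float:
        return float(self.occupancy[0].sum())

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.start_age, self.start_age + self.n_cycles)

    def fracture_events(self) -> dict[str, float]:
        """Total modelled entries into each acute fracture state."""
        return {
            State(s).label: float(self.trackers[:, int(s)].sum()) for s in FRACTURE_STATES
        }


def run_cohort(
    initial: np.ndarray,
    start_age: int,
    gender: str,
    table: TransitionTable,
    horizon_age: int = AGE_MAX,
) -> CohortTrajectory:
    """Propagate ``initial`` from ``start_age`` to ``horizon_age``.

    One matrix application per model year; the matrix used for the
    cycle ending at age ``a + 1`` is the one indexed at age ``a``.
    People still alive at the horizon are censored there.
    """
    if start_age < AGE_MIN:
        raise ValueError(f"start_age must be >= {AGE_MIN}")
    if horizon_age > AGE_MAX:
        raise ValueError(f"horizon_age must be <= {AGE_MAX}")
    if horizon_age < start_age:
        raise ValueError("horizon_age must be >= start_age")
    initial = np.asarray(initial, dtype=float)
    if np.any(initial < 0):
        raise ValueError("initial occupancy must be nonnegative")

    n_cycles = horizon_age - start_age + 1
    occupancy = np.zeros((n_cycles, N_STATES))
    trackers = np.zeros((n_cycles, N_STATES))
    occupancy[0] = initial
    for c in range(1, n_cycles):
        age = start_age + c - 1
        m = table.matrix(gender, age)
        if not np.any(m):
            raise ValueError(f"transition table has no entries at age {age} ({gender})")
        occupancy[c], trackers[c] = step_cohort(occupancy[c - 1], m)
    return CohortTrajectory(gender=gender, start_age=start_age, occupancy=occupancy, trackers=trackers)


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discounting of future costs (default 3%/year)."""

    annual_rate: float = 0.03
    half_cycle: bool = False

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ValueError("annual_rate must be >= 0")


def discount_factor(spec: DiscountSpec, cycle: float) -> float:
    """``(1 + rate)^-cycle`` — present value per unit cost at ``cycle``."""
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    return float((1.0 + spec.annual_rate) ** (-cycle))


# --- microsimulation oracle ------------------------------------------------


@dataclass
class MicrosimResult:
    """Counts from the per-individual simulation, shaped like a trajectory."""

    occupancy: np.ndarray  # (n_cycles, 10) individuals per state
    trackers: np.ndarray  # (n_cycles, 10) entries into each state per cycle
    n_individuals: int
    hip_entries_per_individual: np.ndarray  # (n,) lifetime hip-fracture events
    second_hip_before_first: int  # paths where second_hip precedes first_hip

    def occupancy_fractions(self) -> np.ndarray:
        return self.occupancy / self.n_individuals

    def fracture_events(self) -> dict[str, float]:
        return {
            State(s).label: float(self.trackers[:, int(s)].sum()) for s in FRACTURE_STATES
        }


def microsim_oracle(
    n_individuals: int,
    start_age: int,
    gender: str,
    table: TransitionTable,
    seed: int,
    horizon_age: int = AGE_MAX,
    initial_state: State = State.WELL,
) -> MicrosimResult:
    """Simulate ``n_individuals`` independent paths through ``table``.

    Each individual's next state is drawn from the transition row of
    their current state at their current age; the per-cycle counts are
    the stochastic counterpart of :func:`run_cohort` and converge to it
    by the law of large numbers.  Used in tests as an independent check
    of the deterministic engine.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    n_cycles = horizon_age - start_age + 1
    states = np.full(n_individuals, int(initial_state), dtype=np.int64)
    occupancy = np.zeros((n_cycles, N_STATES))
    trackers = np.zeros((n_cycles, N_STATES))
    hip_entries = np.zeros(n_individuals, dtype=np.int64)
    first_hip_seen = np.zeros(n_individuals, dtype=bool)
    second_before_first = 0

    occupancy[0] = np.bincount(states, minlength=N_STATES)
    for c in range(1, n_cycles):
        age = start_age + c - 1
        cum = np.cumsum(table.matrix(gender, age), axis=1)
        u = rng.random(n_individuals)
        nxt = (u[:, None] > cum[states]).sum(axis=1)
        entered = nxt != states
        trackers[c] = np.bincount(nxt[entered], minlength=N_STATES)
        new_first = entered & (nxt == int(State.FIRST_HIP))
        new_second = entered & (nxt == int(State.SECOND_HIP))
        second_before_first += int(np.sum(new_second & ~first_hip_seen))
        hip_entries += new_first.astype(np.int64) + new_second.astype(np.int64)
        first_hip_seen |= new_first
        states = nxt
        occupancy[c] = np.bincount(states, minlength=N_STATES)

    return MicrosimResult(
        occupancy=occupancy,
        trackers=trackers,
        n_individuals=n_individuals,
        hip_entries_per_individual=hip_entries,
        second_hip_before_first=second_before_first,
    )
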