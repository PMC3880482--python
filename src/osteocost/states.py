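"""Health states and the allowed-transition structure of the fracture model.

The model follows a cohort of people at risk of osteoporotic fractures
through ten health states in one-year cycles: a ``well`` state, an acute
(tunnel) state and a chronic post-fracture state for each of wrist,
vertebral and first/second hip fracture, and absorbing ``death``.  The
acute states are occupied for exactly one cycle so that one-off event
costs and short-term risks can be attached to the fracture year; the
post states carry the long-term elevated re-fracture and mortality risks
and the continuing costs.

A lifetime holds at most two hip fractures.  To make that a structural
guarantee of the transition graph (rather than a soft modelling
convention), the default mask routes patients with a hip-fracture
history only through the hip track: once in ``first_hip`` or beyond,
the only onward fracture event is ``second_hip``.  Fracture events of
lower severity than the current track are not represented (hip is
favoured over vertebral, vertebral over wrist).  The mask is plain data
and may be replaced wholesale through configuration.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = [
    "State",
    "GENDERS",
    "AGE_MIN",
    "AGE_MAX",
    "N_AGES",
    "AGES",
    "FRACTURE_TYPES",
    "FRACTURE_STATES",
    "POST_STATES",
    "HIP_STATES",
    "POST_OF",
    "RESIDUAL_OF",
    "FRACTURE_TYPE_OF",
    "MORTALITY_CONTEXT_OF",
    "default_mask",
    "wage_band",
    "age_band_label",
    "AGE_BANDS",
]


class State(IntEnum):
    """The ten health states, in canonical matrix order."""

    WELL = 0
    WRIST = 1
    POST_WRIST = 2
    VERTEBRAL = 3
    POST_VERTEBRAL = 4
    FIRST_HIP = 5
    POST_FIRST_HIP = 6
    SECOND_HIP = 7
    POST_SECOND_HIP = 8
    DEATH = 9

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "State":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown health state: {label!r}") from None


GENDERS = ("male", "female")

AGE_MIN = 50
AGE_MAX = 99
N_AGES = AGE_MAX - AGE_MIN + 1
AGES = tuple(range(AGE_MIN, AGE_MAX + 1))

#: fracture types, in costing order of increasing severity
FRACTURE_TYPES = ("wrist", "vertebral", "hip")

FRACTURE_STATES = (State.WRIST, State.VERTEBRAL, State.FIRST_HIP, State.SECOND_HIP)
POST_STATES = (
    State.POST_WRIST,
    State.POST_VERTEBRAL,
    State.POST_FIRST_HIP,
    State.POST_SECOND_HIP,
)
HIP_STATES = (
    State.FIRST_HIP,
    State.POST_FIRST_HIP,
    State.SECOND_HIP,
    State.POST_SECOND_HIP,
)

#: acute state -> its chronic post state
POST_OF = {
    State.WRIST: State.POST_WRIST,
    State.VERTEBRAL: State.POST_VERTEBRAL,
    State.FIRST_HIP: State.POST_FIRST_HIP,
    State.SECOND_HIP: State.POST_SECOND_HIP,
}

#: where the probability mass not claimed by a fracture or death goes
RESIDUAL_OF = {
    State.WELL: State.WELL,
    State.WRIST: State.POST_WRIST,
    State.POST_WRIST: State.POST_WRIST,
    State.VERTEBRAL: State.POST_VERTEBRAL,
    State.POST_VERTEBRAL: State.POST_VERTEBRAL,
    State.FIRST_HIP: State.POST_FIRST_HIP,
    State.POST_FIRST_HIP: State.POST_FIRST_HIP,
    State.SECOND_HIP: State.POST_SECOND_HIP,
    State.POST_SECOND_HIP: State.POST_SECOND_HIP,
    State.DEATH: State.DEATH,
}

#: fracture (acute) state -> incidence-rate fracture type
FRACTURE_TYPE_OF = {
    State.WRIST: "wrist",
    State.VERTEBRAL: "vertebral",
    State.FIRST_HIP: "hip",
    State.SECOND_HIP: "hip",
}

#: state whose mortality relative risk applies while occupying each state.
#: Acute fracture states already carry the elevated mortality of their
#: post-fracture context (the excess risk starts in the fracture year).
MORTALITY_CONTEXT_OF = {
    State.WELL: State.WELL,
    State.WRIST: State.POST_WRIST,
    State.POST_WRIST: State.POST_WRIST,
    State.VERTEBRAL: State.POST_VERTEBRAL,
    State.POST_VERTEBRAL: State.POST_VERTEBRAL,
    State.FIRST_HIP: State.POST_FIRST_HIP,
    State.POST_FIRST_HIP: State.POST_FIRST_HIP,
    State.SECOND_HIP: State.POST_SECOND_HIP,
    State.POST_SECOND_HIP: State.POST_SECOND_HIP,
}

#: fracture destinations reachable from each live state under the default
#: severity-ordered mask (see module docstring)
_ALLOWED_FRACTURES = {
    State.WELL: (State.WRIST, State.VERTEBRAL, State.FIRST_HIP),
    State.WRIST: (State.VERTEBRAL, State.FIRST_HIP),
    State.POST_WRIST: (State.WRIST, State.VERTEBRAL, State.FIRST_HIP),
    State.VERTEBRAL: (State.FIRST_HIP,),
    State.POST_VERTEBRAL: (State.WRIST, State.VERTEBRAL, State.FIRST_HIP),
    State.FIRST_HIP: (State.SECOND_HIP,),
    State.POST_FIRST_HIP: (State.SECOND_HIP,),
    State.SECOND_HIP: (),
    State.POST_SECOND_HIP: (),
}


def default_mask() -> np.ndarray:
    """Boolean (10, 10) array of permitted one-cycle transitions.

    ``mask[i, j]`` is True when occupancy may flow from state ``i`` to
    state ``j``.  Every live state may die or fall through to its
    residual destination; fracture events follow the severity-ordered
    edge set above; death is absorbing.
    """
    mask = np.zeros((len(State), len(State)), dtype=bool)
    for s in State:
        if s is State.DEATH:
            mask[s, State.DEATH] = True
            continue
        mask[s, RESIDUAL_OF[s]] = True
        mask[s, State.DEATH] = True
        for dest in _ALLOWED_FRACTURES[s]:
            mask[s, dest] = True
    return mask


def allowed_fracture_destinations(state: State) -> tuple:
    """Fracture states reachable from ``state`` under the default mask."""
    return _ALLOWED_FRACTURES[state]


# --- age banding -----------------------------------------------------------

#: five-year reporting bands spanning the model horizon
AGE_BANDS = tuple(f"{a}-{a + 4}" for a in range(AGE_MIN, AGE_MAX, 5))


def age_band_label(age: int) -> str:
    """Five-year reporting band containing ``age`` (e.g. 83 -> '80-84')."""
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValueError(f"age {age} outside model range [{AGE_MIN}, {AGE_MAX}]")
    lo = AGE_MIN + 5 * ((age - AGE_MIN) // 5)
    return f"{lo}-{lo + 4}"


def wage_band(age: int) -> str:
    """Wage-table band for ``age``: '50-54', '55-59', '60-64' or '65+'."""
    if age < 50:
        raise ValueError(f"age {age} below model range")
    if age >= 65:
        return "65+"
    lo = 50 + 5 * ((age - 50) // 5)
    return f"{lo}-{lo + 4}"
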