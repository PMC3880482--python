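import numpy as np
import pandas as pd
import pytest

from osteocost.markov import N_STATES, TransitionTable
from osteocost.states import GENDERS, N_AGES, RESIDUAL_OF, State
from osteocost.synthetic import SyntheticConfig, generate_demography, generate_epidemiology
from osteocost.transitions import build_table


def make_table(rows: dict | None = None) -> TransitionTable:
    """A transition table applying the same hand-specified matrix everywhere.

    ``rows`` maps a State to its (10,) probability row; unspecified
    states default to sending everyone to their residual destination
    (self for well/post states, the post state for acute tunnels,
    death for death), which satisfies every table invariant.
    """
    m = np.zeros((N_STATES, N_STATES))
    for s in State:
        m[int(s), int(RESIDUAL_OF[s])] = 1.0
    if rows:
        for s, row in rows.items():
            m[int(s)] = np.asarray(row, dtype=float)
    p = np.broadcast_to(m, (len(GENDERS), N_AGES, N_STATES, N_STATES)).copy()
    return TransitionTable(p)


def row(**probs) -> np.ndarray:
    """Build a (10,) row from state-label keyword probabilities."""
    out = np.zeros(N_STATES)
    for label, p in probs.items():
        out[int(State.from_label(label))] = p
    return out


@pytest.fixture(scope="session")
def syn_cfg() -> SyntheticConfig:
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def epi(syn_cfg):
    return generate_epidemiology(syn_cfg)


@pytest.fixture(scope="session")
def demography(syn_cfg) -> pd.DataFrame:
    return generate_demography(syn_cfg)


@pytest.fixture(scope="session")
def syn_table(epi) -> TransitionTable:
    return build_table(epi)
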