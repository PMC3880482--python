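"""Synthetic registry-like inputs for running and testing the model.

The real analysis draws fracture incidence from a national hospital
discharge register, mortality and demography from national statistics,
and relative risks from the literature.  None of those microdata ship
with the package, so this module generates inputs with the same
statistical structure:

* log-linear incidence in age per fracture type (hip steepest), with
  female rates at or above male rates for wrist and hip;
* Gompertz–Makeham background mortality, strictly increasing in age;
* literature-scale relative risks (re-fracture about 2, post-hip
  mortality 2–3);
* a declining population pyramid over the 50–99 range whose at-risk
  counts calibrate exactly to the published cohort sizes (149,466 men
  and 388,474 women).

A single integer seed drives the only randomness (mild jitter on the
incidence parameters), so a fixed seed reproduces files byte for byte.
Levels are structural stand-ins, not national estimates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markov import N_STATES
from .states import AGE_BANDS, AGE_MIN, AGES, FRACTURE_TYPES, GENDERS, N_AGES, State
from .transitions import EpidemiologyInputs

__all__ = [
    "SyntheticConfig",
    "generate_epidemiology",
    "generate_demography",
    "write_inputs",
    "load_inputs",
]

#: per-fracture-type incidence at age 50 (events/person-year) and
#: exponential age slope (per year); hip rises steepest, female wrist
#: and hip exceed male
_DEFAULT_INCIDENCE = {
    "wrist": {"base": {"male": 1.0e-3, "female": 3.0e-3}, "slope": 0.030},
    "vertebral": {"base": {"male": 8.0e-4, "female": 1.2e-3}, "slope": 0.050},
    "hip": {"base": {"male": 4.0e-4, "female": 6.0e-4}, "slope": 0.110},
}

#: Gompertz–Makeham parameters: rate(age) = makeham + gompertz_b * exp(gompertz_theta * (age - 50))
_DEFAULT_MORTALITY = {
    "male": {"makeham": 1.0e-3, "gompertz_b": 4.0e-3, "gompertz_theta": 0.095},
    "female": {"makeham": 8.0e-4, "gompertz_b": 2.5e-3, "gompertz_theta": 0.100},
}

#: re-fracture relative risk by (post state, fracture type); omitted pairs are 1
_DEFAULT_RR_REFRACTURE = {
    ("post_wrist", "wrist"): 2.0,
    ("post_wrist", "vertebral"): 1.8,
    ("post_wrist", "hip"): 1.8,
    ("post_vertebral", "vertebral"): 2.2,
    ("post_vertebral", "hip"): 2.3,
    ("post_vertebral", "wrist"): 1.5,
    ("post_first_hip", "hip"): 2.5,
}

#: mortality relative risk by post state
_DEFAULT_RR_DEATH = {
    "post_wrist": 1.0,
    "post_vertebral": 1.8,
    "post_first_hip": 2.5,
    "post_second_hip": 3.0,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic input generator."""

    seed: int = 0
    incidence: dict = field(default_factory=lambda: _deep_copy(_DEFAULT_INCIDENCE))
    mortality: dict = field(default_factory=lambda: _deep_copy(_DEFAULT_MORTALITY))
    rr_refracture: dict = field(default_factory=lambda: dict(_DEFAULT_RR_REFRACTURE))
    rr_death: dict = field(default_factory=lambda: dict(_DEFAULT_RR_DEATH))
    incidence_jitter_sd: float = 0.05  # lognormal sd on base rates, shared across genders
    population_50: dict = field(
        default_factory=lambda: {"male": 180_000, "female": 190_000}
    )
    population_decline: float = 0.045  # exponential decline of band population with age
    at_risk_frac: dict = field(default_factory=lambda: {"male": 0.177, "female": 0.408})
    calibrate_at_risk: bool = True
    at_risk_target: dict = field(
        default_factory=lambda: {"male": 149_466, "female": 388_474}
    )


def _deep_copy(d: dict) -> dict:
    import copy

    return copy.deepcopy(d)


def generate_epidemiology(cfg: SyntheticConfig) -> EpidemiologyInputs:
    """Generate incidence, mortality and relative-risk inputs.

    The seeded jitter multiplies each fracture type's base rate by a
    lognormal factor shared across genders, so the female-at-or-above-
    male ordering and the within-curve monotonicity are preserved
    exactly; the output is deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    ages = np.asarray(AGES, dtype=float)
    incidence = np.zeros((len(GENDERS), N_AGES, len(FRACTURE_TYPES)))
    for ti, ftype in enumerate(FRACTURE_TYPES):
        params = cfg.incidence[ftype]
        slope = float(params["slope"])
        if slope < 0:
            raise ValueError(f"incidence slope for {ftype} must be >= 0, got {slope}")
        jitter = (
            float(np.exp(rng.normal(0.0, cfg.incidence_jitter_sd)))
            if cfg.incidence_jitter_sd > 0
            else 1.0
        )
        for gi, gender in enumerate(GENDERS):
            base = float(params["base"][gender])
            if base < 0:
                raise ValueError(f"incidence base for {ftype}/{gender} must be >= 0")
            incidence[gi, :, ti] = base * jitter * np.exp(slope * (ages - AGE_MIN))

    mortality = np.zeros((len(GENDERS), N_AGES))
    for gi, gender in enumerate(GENDERS):
        p = cfg.mortality[gender]
        if p["gompertz_b"] <= 0 or p["gompertz_theta"] <= 0:
            raise ValueError("Gompertz parameters must be positive")
        mortality[gi] = p["makeham"] + p["gompertz_b"] * np.exp(
            p["gompertz_theta"] * (ages - AGE_MIN)
        )

    rr_refracture = np.ones((N_STATES, len(FRACTURE_TYPES)))
    ftype_idx = {t: i for i, t in enumerate(FRACTURE_TYPES)}
    for (state_label, ftype), value in cfg.rr_refracture.items():
        rr_refracture[int(State.from_label(state_label)), ftype_idx[ftype]] = value
    rr_death = np.ones(N_STATES)
    for state_label, value in cfg.rr_death.items():
        rr_death[int(State.from_label(state_label))] = value

    return EpidemiologyInputs(incidence, mortality, rr_refracture, rr_death)


def generate_demography(cfg: SyntheticConfig) -> pd.DataFrame:
    """Population and at-risk counts per gender and five-year band.

    Band populations decline exponentially with age from the
    ``population_50`` level.  With calibration on (default), the
    integer at-risk counts are scaled by largest-remainder rounding to
    sum exactly to the published cohort targets, and populations are
    back-computed from the at-risk fraction.
    """
    rows = []
    for gender in GENDERS:
        base = float(cfg.population_50[gender])
        raw = np.array(
            [base * np.exp(-cfg.population_decline * (5 * i)) for i in range(len(AGE_BANDS))]
        )
        frac = float(cfg.at_risk_frac[gender])
        if cfg.calibrate_at_risk and raw.sum() > 0 and frac > 0:
            target = int(cfg.at_risk_target[gender])
            at_risk = _largest_remainder(raw / raw.sum() * target)
            population = np.rint(at_risk / frac).astype(np.int64)
        else:
            population = np.rint(raw).astype(np.int64)
            at_risk = np.rint(population * frac).astype(np.int64)
        for band, pop, risk in zip(AGE_BANDS, population, at_risk):
            rows.append(
                {"gender": gender, "age_band": band, "population": int(pop), "at_risk": int(risk)}
            )
    return pd.DataFrame(rows)


def _largest_remainder(quotas: np.ndarray) -> np.ndarray:
    """Round nonnegative quotas to integers preserving their exact sum."""
    floors = np.floor(quotas).astype(np.int64)
    remainder = int(round(quotas.sum())) - int(floors.sum())
    order = np.argsort(-(quotas - floors))
    out = floors.copy()
    out[order[:remainder]] += 1
    return out


def write_inputs(cfg: SyntheticConfig, outdir) -> dict[str, Path]:
    """Generate and write all input files; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    epi = generate_epidemiology(cfg)
    paths = {
        "incidence": outdir / "incidence.csv",
        "mortality": outdir / "mortality.csv",
        "relative_risks": outdir / "relative_risks.csv",
        "demography": outdir / "demography.csv",
    }
    epi.to_files(paths["incidence"], paths["mortality"], paths["relative_risks"])
    generate_demography(cfg).to_csv(paths["demography"], index=False)
    return paths


def load_inputs(indir) -> tuple[EpidemiologyInputs, pd.DataFrame]:
    """Read back the files written by :func:`write_inputs`."""
    indir = Path(indir)
    epi = EpidemiologyInputs.from_files(
        indir / "incidence.csv", indir / "mortality.csv", indir / "relative_risks.csv"
    )
    demography = pd.read_csv(indir / "demography.csv")
    return epi, demography
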