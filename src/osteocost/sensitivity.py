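"""One-way deterministic sensitivity analysis (tornado ranking).

Each scenario perturbs a single configuration scalar to a low and a
high value, re-runs the full pipeline with everything else held at
baseline, and records the outcome at both ends.  Ranking the scenarios
by outcome span (descending) yields the familiar tornado diagram
ordering: the widest bar is the parameter the result is most sensitive
to.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd
import yaml

from .config import ModelConfig, resolve_path

__all__ = [
    "ParamScenario",
    "TornadoEntry",
    "one_way_sa",
    "default_scenarios",
    "load_scenarios",
    "save_scenarios",
    "tornado_frame",
]


@dataclass(frozen=True)
class ParamScenario:
    """Low/high bounds for one configuration scalar."""

    path: str
    low: float
    high: float
    baseline: float | None = None  # taken from the config when omitted

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"scenario {self.path!r}: low {self.low} > high {self.high}")
        if self.baseline is not None and not self.low <= self.baseline <= self.high:
            raise ValueError(
                f"scenario {self.path!r}: baseline {self.baseline} outside "
                f"[{self.low}, {self.high}]"
            )


@dataclass(frozen=True)
class TornadoEntry:
    """Outcome at the two ends of one scenario; span ranks the tornado."""

    path: str
    baseline_value: float
    outcome_low: float
    outcome_high: float

    @property
    def span(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def one_way_sa(
    scenarios: Sequence[ParamScenario],
    runner: Callable[[ModelConfig], float],
    config: ModelConfig,
) -> tuple[float, list[TornadoEntry]]:
    """Run every scenario through ``runner`` and rank by outcome span.

    ``runner`` maps a configuration to the scalar outcome (typically
    total discounted lifetime cost) and must be deterministic.  Returns
    the baseline outcome and entries sorted by span, widest first (ties
    keep scenario order).
    """
    baseline_outcome = runner(config)
    entries: list[TornadoEntry] = []
    for sc in scenarios:
        base_val = resolve_path(config, sc.path)  # raises naming the path
        out_low = runner(config.replace_value(sc.path, sc.low))
        out_high = runner(config.replace_value(sc.path, sc.high))
        entries.append(
            TornadoEntry(
                path=sc.path,
                baseline_value=float(base_val),
                outcome_low=out_low,
                outcome_high=out_high,
            )
        )
    entries.sort(key=lambda e: -e.span)
    return baseline_outcome, entries


def default_scenarios(config: ModelConfig) -> list[ParamScenario]:
    """The shipped scenario set.

    The one empirically grounded interval — incremental personal care
    varied between 3.4 and 6.55 hours per week — plus ±25% bands on
    every monetary unit cost.
    """
    scenarios = [ParamScenario("pathways.personal_care_hours_per_week", 3.4, 6.55)]
    for f in dataclasses.fields(config.unit_costs):
        if f.name in ("currency", "base_year", "daily_wage"):
            continue
        value = getattr(config.unit_costs, f.name)
        scenarios.append(
            ParamScenario(f"unit_costs.{f.name}", 0.75 * value, 1.25 * value)
        )
    return scenarios


def save_scenarios(scenarios: Iterable[ParamScenario], path) -> None:
    data = [dataclasses.asdict(s) for s in scenarios]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_scenarios(path) -> list[ParamScenario]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or []
    return [ParamScenario(**item) for item in data]


def tornado_frame(baseline: float, entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    """Delimited-text-ready tornado table, sorted by span descending."""
    return pd.DataFrame(
        [
            {
                "parameter": e.path,
                "baseline_value": e.baseline_value,
                "outcome_low": e.outcome_low,
                "outcome_high": e.outcome_high,
                "span": e.span,
                "baseline_outcome": baseline,
            }
            for e in entries
        ]
    )
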