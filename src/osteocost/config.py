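"""Structured run configuration with YAML round-tripping.

One object bundles everything a deterministic model run depends on:
unit costs, pathway parameters, the discount specification, the
at-risk fractions and the relative-risk scale.  Dot-separated paths
(``"pathways.personal_care_hours_per_week"``) address individual
scalars for overrides and sensitivity analysis.  Unknown keys in a
config file are rejected rather than silently ignored.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

from .costs import PathwayParams, UnitCostTable
from .markov import DiscountSpec

__all__ = ["ModelConfig", "resolve_path", "set_path", "config_digest"]


@dataclass
class ModelConfig:
    """Everything that parameterises a costed model run."""

    unit_costs: UnitCostTable = field(default_factory=UnitCostTable)
    pathways: PathwayParams = field(default_factory=PathwayParams)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    at_risk_frac: dict = field(default_factory=lambda: {"male": 0.177, "female": 0.408})
    rr_scale: str = "hazard"  # how relative risks act on probabilities

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        data = copy.deepcopy(dict(data))
        kwargs = {}
        nested = {"unit_costs": UnitCostTable, "pathways": PathwayParams, "discount": DiscountSpec}
        for key, subcls in nested.items():
            if key in data:
                sub = data.pop(key)
                _check_keys(subcls, sub, key)
                sub = _coerce_tuples(subcls, sub)
                kwargs[key] = subcls(**sub)
        for key in ("at_risk_frac", "rr_scale"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ValueError(f"unknown configuration keys: {sorted(data)}")
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def replace_value(self, dotted_path: str, value) -> "ModelConfig":
        """A deep copy of this config with one scalar replaced."""
        clone = copy.deepcopy(self)
        set_path(clone, dotted_path, value)
        return clone


def _check_keys(subcls, data: dict, where: str) -> None:
    known = {f.name for f in dataclasses.fields(subcls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys under {where!r}: {sorted(unknown)}")


def _coerce_tuples(subcls, data: dict) -> dict:
    # YAML has no tuples; restore them where the dataclass default is one
    out = dict(data)
    for f in dataclasses.fields(subcls):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = tuple(out[f.name])
    return out


def resolve_path(obj, dotted_path: str):
    """Fetch the value at a dot-separated attribute/key path."""
    cur = obj
    for part in dotted_path.split("."):
        if isinstance(cur, dict):
            if part not in cur:
                raise KeyError(f"cannot resolve {dotted_path!r}: no key {part!r}")
            cur = cur[part]
        elif dataclasses.is_dataclass(cur) or hasattr(cur, part):
            if not hasattr(cur, part):
                raise KeyError(f"cannot resolve {dotted_path!r}: no attribute {part!r}")
            cur = getattr(cur, part)
        else:
            raise KeyError(f"cannot resolve {dotted_path!r} at segment {part!r}")
    return cur


def set_path(obj, dotted_path: str, value) -> None:
    """Set the scalar at a dot-separated path, in place."""
    parts = dotted_path.split(".")
    parent = resolve_path(obj, ".".join(parts[:-1])) if len(parts) > 1 else obj
    leaf = parts[-1]
    if isinstance(parent, dict):
        if leaf not in parent:
            raise KeyError(f"cannot resolve {dotted_path!r}: no key {leaf!r}")
        parent[leaf] = value
    else:
        if not hasattr(parent, leaf):
            raise KeyError(f"cannot resolve {dotted_path!r}: no attribute {leaf!r}")
        if dataclasses.is_dataclass(parent) and getattr(parent, "__dataclass_params__").frozen:
            object.__setattr__(parent, leaf, value)
        else:
            setattr(parent, leaf, value)


def config_digest(config: ModelConfig) -> str:
    """Stable SHA-256 digest of the canonical YAML form."""
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()
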