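"""Read and write model configurations (YAML).

The schema mirrors the dataclass fields in :mod:`markovcua.model` one to
one, so ``read_model(write_model(m)) == m`` holds field-for-field.  Parsing
is strict: missing required keys, unknown keys, malformed numbers and
references to undeclared states are rejected with messages naming the
offending key.
"""

from __future__ import annotations

import numbers
from pathlib import Path

import yaml

from .model import (
    ANY_ALIVE,
    HealthState,
    ModelDefinition,
    ModelSettings,
    StrategyDefinition,
    TransitionRule,
)

__all__ = ["read_model", "write_model", "model_to_dict", "model_from_dict", "ConfigError"]


class ConfigError(ValueError):
    """A model configuration file is malformed."""


def _num(mapping: dict, key: str, where: str, default=None, required=True):
    if key not in mapping:
        if required:
            raise ConfigError(f"{where}: missing required key {key!r}")
        return default
    v = mapping[key]
    if v is None and not required:
        return None
    if isinstance(v, bool) or not isinstance(v, numbers.Real):
        raise ConfigError(f"{where}: key {key!r} must be a number, got {v!r}")
    return float(v)


def _str(mapping: dict, key: str, where: str, default=None, required=True):
    if key not in mapping:
        if required:
            raise ConfigError(f"{where}: missing required key {key!r}")
        return default
    v = mapping[key]
    if not isinstance(v, str):
        raise ConfigError(f"{where}: key {key!r} must be a string, got {v!r}")
    return v


def _bool(mapping: dict, key: str, where: str, default=False):
    v = mapping.get(key, default)
    if not isinstance(v, bool):
        raise ConfigError(f"{where}: key {key!r} must be a boolean, got {v!r}")
    return v


def _state_from_dict(d: dict) -> HealthState:
    if not isinstance(d, dict):
        raise ConfigError(f"states: each entry must be a mapping, got {d!r}")
    sid = _str(d, "id", "states")
    where = f"state {sid!r}"
    return HealthState(
        id=sid,
        label=_str(d, "label", where, default="", required=False),
        utility=_num(d, "utility", where, default=0.0, required=False),
        extra_cycle_cost=_num(d, "extra_cycle_cost", where, default=0.0, required=False),
        entry_cost=_num(d, "entry_cost", where, default=0.0, required=False),
        followup=_str(d, "followup", where, default="standard", required=False),
        followup_override_year1=_num(d, "followup_override_year1", where, required=False),
        followup_override_later=_num(d, "followup_override_later", where, required=False),
        is_absorbing=_bool(d, "is_absorbing", where),
        is_terminal_care=_bool(d, "is_terminal_care", where),
    )


def _rule_from_dict(d: dict) -> TransitionRule:
    if not isinstance(d, dict):
        raise ConfigError(f"rules: each entry must be a mapping, got {d!r}")
    frm = _str(d, "from", "rules")
    to = _str(d, "to", "rules")
    where = f"rule {frm}->{to}"
    prob = d.get("probability", "__missing__")
    if prob == "__missing__":
        raise ConfigError(f"{where}: missing required key 'probability'")
    if prob is not None and prob != "remainder":
        if isinstance(prob, bool) or not isinstance(prob, numbers.Real):
            raise ConfigError(f"{where}: probability must be a number, null or 'remainder'")
        prob = float(prob)
    else:
        prob = None
    we = d.get("window_end")
    if we is not None:
        we = int(_num({"window_end": we}, "window_end", where))
    return TransitionRule(
        strategy=_str(d, "strategy", where, default="shared", required=False),
        from_state=frm,
        to_state=to,
        probability=prob,
        window_start=int(_num(d, "window_start", where, default=1.0, required=False)),
        window_end=we,
        perturbable=_bool(d, "perturbable", where, default=True),
    )


def model_from_dict(doc: dict) -> ModelDefinition:
    """Build a :class:`ModelDefinition` from a parsed configuration mapping."""
    if not isinstance(doc, dict):
        raise ConfigError("top level of a model configuration must be a mapping")
    for key in ("states", "rules", "strategies", "settings", "start_state"):
        if key not in doc:
            raise ConfigError(f"missing required top-level key {key!r}")

    sd = doc["settings"]
    if not isinstance(sd, dict):
        raise ConfigError("settings must be a mapping")
    settings = ModelSettings(
        cycle_length_months=_num(sd, "cycle_length_months", "settings", default=3.0, required=False),
        horizon_cycles=int(_num(sd, "horizon_cycles", "settings")),
        annual_discount_rate=_num(sd, "annual_discount_rate", "settings", default=0.0, required=False),
        wtp_threshold=_num(sd, "wtp_threshold", "settings", default=7_500_000.0, required=False),
        half_cycle_correction=_bool(sd, "half_cycle_correction", "settings"),
        followup_cost_year1=_num(sd, "followup_cost_year1", "settings", default=0.0, required=False),
        followup_cost_later=_num(sd, "followup_cost_later", "settings", default=0.0, required=False),
        admission_cost=_num(sd, "admission_cost", "settings", default=0.0, required=False),
        followup_in_first_cycle=_bool(sd, "followup_in_first_cycle", "settings"),
    )

    states = [_state_from_dict(s) for s in doc["states"]]
    rules = [_rule_from_dict(r) for r in doc["rules"]]
    strategies = []
    for a in doc["strategies"]:
        aid = _str(a, "id", "strategies")
        strategies.append(
            StrategyDefinition(
                id=aid,
                treatment_fee=_num(a, "treatment_fee", f"strategy {aid!r}"),
                fee_fixed=_bool(a, "fee_fixed", f"strategy {aid!r}"),
            )
        )

    model = ModelDefinition(
        states=states,
        rules=rules,
        strategies=strategies,
        settings=settings,
        start_state=_str(doc, "start_state", "top level"),
        utility_orderings=[list(c) for c in doc.get("utility_orderings", [])],
        param_links=[list(g) for g in doc.get("param_links", [])],
    )

    ids = {s.id for s in states}
    if "death" not in ids:
        raise ConfigError("configuration declares no 'death' state")
    for r in rules:
        for ref in (r.from_state, r.to_state):
            if ref != ANY_ALIVE and ref not in ids:
                raise ConfigError(
                    f"rule {r.from_state}->{r.to_state}: unknown state reference {ref!r}"
                )
        if r.probability is not None and not (0.0 <= r.probability <= 1.0):
            raise ConfigError(
                f"rule {r.from_state}->{r.to_state} ({r.strategy}): "
                f"probability {r.probability} outside [0, 1]"
            )
    if model.start_state not in ids:
        raise ConfigError(f"start_state {model.start_state!r} is not a declared state")
    return model


def model_to_dict(model: ModelDefinition) -> dict:
    def state_dict(s: HealthState) -> dict:
        d = {
            "id": s.id,
            "label": s.label,
            "utility": s.utility,
            "extra_cycle_cost": s.extra_cycle_cost,
            "entry_cost": s.entry_cost,
            "followup": s.followup,
            "is_absorbing": s.is_absorbing,
            "is_terminal_care": s.is_terminal_care,
        }
        if s.followup_override_year1 is not None:
            d["followup_override_year1"] = s.followup_override_year1
        if s.followup_override_later is not None:
            d["followup_override_later"] = s.followup_override_later
        return d

    def rule_dict(r: TransitionRule) -> dict:
        d = {
            "strategy": r.strategy,
            "from": r.from_state,
            "to": r.to_state,
            "probability": "remainder" if r.probability is None else r.probability,
            "window_start": r.window_start,
        }
        if r.window_end is not None:
            d["window_end"] = r.window_end
        if not r.perturbable:
            d["perturbable"] = False
        return d

    return {
        "settings": {
            "cycle_length_months": model.settings.cycle_length_months,
            "horizon_cycles": model.settings.horizon_cycles,
            "annual_discount_rate": model.settings.annual_discount_rate,
            "wtp_threshold": model.settings.wtp_threshold,
            "half_cycle_correction": model.settings.half_cycle_correction,
            "followup_cost_year1": model.settings.followup_cost_year1,
            "followup_cost_later": model.settings.followup_cost_later,
            "admission_cost": model.settings.admission_cost,
            "followup_in_first_cycle": model.settings.followup_in_first_cycle,
        },
        "start_state": model.start_state,
        "strategies": [
            {"id": a.id, "treatment_fee": a.treatment_fee, "fee_fixed": a.fee_fixed}
            for a in model.strategies
        ],
        "states": [state_dict(s) for s in model.states],
        "rules": [rule_dict(r) for r in model.rules],
        "utility_orderings": [list(c) for c in model.utility_orderings],
        "param_links": [list(g) for g in model.param_links],
    }


def read_model(path: str | Path) -> ModelDefinition:
    """Load a model configuration from a YAML file."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:  # pragma: no cover - passthrough
            raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    return model_from_dict(doc)


def write_model(model: ModelDefinition, path: str | Path) -> None:
    """Write a model configuration to a YAML file (round-trip safe)."""
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)
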