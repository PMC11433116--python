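"""One-way (tornado) sensitivity analysis.

Each scalar parameter is moved to 80% and 120% of its base value (the
published perturbation band), the incremental cost-effectiveness ratio is
recomputed at each end, and parameters are ranked by the width of the
resulting ICER interval.  Perturbations that would leave the feasible
region (utilities or probabilities above 1, outgoing probability rows
above 1) are clamped to the boundary and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cea import run_model
from .model import ModelDefinition, copy_model
from .packaged import packaged_model
from .params import Parameter, _row_groups, _row_violations, enumerate_parameters

__all__ = ["OwsaEntry", "tornado", "run_owsa", "tornado_frame"]

PERTURBATION = 0.2


@dataclass
class OwsaEntry:
    parameter_id: str
    kind: str
    base_value: float
    low_value: float
    high_value: float
    icer_at_low: float | None
    icer_at_high: float | None
    icer_range: float
    clamped: bool
    linked_ids: tuple[str, ...] = ()


def _feasible_value(model: ModelDefinition, param: Parameter, value: float) -> tuple[float, bool]:
    """Clamp a perturbed value to the model's feasible region."""
    clamped = False
    if param.clamp_high is not None and value > param.clamp_high:
        value, clamped = param.clamp_high, True
    if param.kind == "probability" and value > param.base:
        param.set(model, value)
        groups = _row_groups(model)
        if _row_violations(model, groups):
            # shrink to the largest value keeping every row sum at 1
            horizon = model.settings.horizon_cycles
            headroom = value
            for (strategy, src), idxs in groups.items():
                rules = [model.rules[i] for i in idxs]
                targets = {t[1] for t in param.targets}
                if not targets & set(idxs):
                    continue
                for c in {min(r.window_start, horizon) for r in rules}:
                    active = [
                        (i, r)
                        for i, r in zip(idxs, rules)
                        if r.window_start <= c <= (r.window_end if r.window_end is not None else horizon)
                    ]
                    if not any(i in targets for i, _ in active):
                        continue
                    others = sum(r.probability for i, r in active if i not in targets)
                    headroom = min(headroom, max(1.0 - others, 0.0))
            value, clamped = headroom, True
    return value, clamped


def tornado(
    model: ModelDefinition,
    comparator: str = "PBT",
    reference: str = "3DCRT",
    perturbation: float = PERTURBATION,
) -> list[OwsaEntry]:
    """One entry per scalar parameter, sorted by descending ICER range.

    Ties (notably the zero-base parameters, whose range is empty) are
    broken lexicographically by parameter id.
    """
    entries = []
    for param in enumerate_parameters(model):
        icers = {}
        values = {}
        clamped = False
        for side, factor in (("low", 1 - perturbation), ("high", 1 + perturbation)):
            m = copy_model(model)
            v, c = _feasible_value(m, param, param.base * factor)
            clamped |= c
            param.set(m, v)
            values[side] = v
            res = run_model(m, comparator, reference, check=False)
            icers[side] = res.cea.icer
        if icers["low"] is None or icers["high"] is None:
            rng = float("inf")
        else:
            rng = abs(icers["high"] - icers["low"])
        entries.append(
            OwsaEntry(
                parameter_id=param.id,
                kind=param.kind,
                base_value=param.base,
                low_value=values["low"],
                high_value=values["high"],
                icer_at_low=icers["low"],
                icer_at_high=icers["high"],
                icer_range=rng,
                clamped=clamped,
                linked_ids=param.linked_ids,
            )
        )
    entries.sort(key=lambda e: (-e.icer_range, e.parameter_id))
    return entries


def run_owsa(fee_level: str = "rare", perturbation: float = PERTURBATION) -> list[OwsaEntry]:
    """Tornado analysis of the packaged model at one fee level."""
    return tornado(packaged_model(fee_level), perturbation=perturbation)


def tornado_frame(entries: list[OwsaEntry]) -> pd.DataFrame:
    """Tabular (CSV-ready) view of a tornado analysis."""
    return pd.DataFrame(
        {
            "parameter": [e.parameter_id for e in entries],
            "kind": [e.kind for e in entries],
            "base": [e.base_value for e in entries],
            "low": [e.low_value for e in entries],
            "high": [e.high_value for e in entries],
            "icer_low": [e.icer_at_low for e in entries],
            "icer_high": [e.icer_at_high for e in entries],
            "icer_range": [e.icer_range for e in entries],
            "clamped": [e.clamped for e in entries],
        }
    )
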