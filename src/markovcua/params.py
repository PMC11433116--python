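"""Scalar parameter registry and triangular sampling.

Sensitivity analyses treat the model as a flat vector of scalar
parameters: one per utility weight, one per cost figure and one per
literal transition probability.  The registry enumerates them with stable
ids (``utility.<state>``, ``cost.entry.<state>``,
``prob.<arm>.<from>><to>``, ...), honours the model's ``param_links``
(several scalars published as a single figure are perturbed jointly), and
provides the triangular-distribution sampler used by probabilistic
sensitivity analysis: each scalar with base ``b`` is drawn from
``Triangular(b(1-w), b, b(1+w))`` with ``w = 0.2`` by default, utilities
and probabilities are clamped at 1, the model's utility grade-ordering
chains are enforced by redrawing violating families, and draws that push
an outgoing probability row above 1 are redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelDefinition, copy_model

__all__ = ["Parameter", "enumerate_parameters", "sample_draw", "DrawFlags"]

# A target is (container, index_or_None, attribute).
_Target = tuple[str, int | None, str]


@dataclass
class Parameter:
    """One independently perturbable scalar of a model."""

    id: str
    kind: str  # "utility" | "cost" | "probability"
    base: float
    targets: list[_Target]
    clamp_high: float | None = None
    linked_ids: tuple[str, ...] = ()

    def get(self, model: ModelDefinition) -> float:
        return _get_target(model, self.targets[0])

    def set(self, model: ModelDefinition, value: float) -> None:
        for t in self.targets:
            _set_target(model, t, value)


def _get_target(model: ModelDefinition, target: _Target) -> float:
    container, idx, attr = target
    if container == "state":
        return getattr(model.states[idx], attr)
    if container == "rule":
        return getattr(model.rules[idx], attr)
    if container == "strategy":
        return getattr(model.strategies[idx], attr)
    if container == "settings":
        return getattr(model.settings, attr)
    raise ValueError(f"unknown target container {container!r}")


def _set_target(model: ModelDefinition, target: _Target, value: float) -> None:
    container, idx, attr = target
    if container == "state":
        setattr(model.states[idx], attr, value)
    elif container == "rule":
        setattr(model.rules[idx], attr, value)
    elif container == "strategy":
        setattr(model.strategies[idx], attr, value)
    elif container == "settings":
        setattr(model.settings, attr, value)
    else:
        raise ValueError(f"unknown target container {container!r}")


def enumerate_parameters(model: ModelDefinition) -> list[Parameter]:
    """All perturbable scalars of a model, in a stable order.

    Utilities first (state order), then costs, then transition
    probabilities (rule order).  Remainder rules, the death state's
    utility and scenario-defining fixed fees are excluded.  Zero-valued
    probabilities are included (their perturbation range is empty but
    they are published scalars); zero-valued optional costs are not.
    ``param_links`` groups are merged into single parameters.
    """
    params: list[Parameter] = []

    for i, s in enumerate(model.states):
        if s.id == "death":
            continue
        params.append(
            Parameter(f"utility.{s.id}", "utility", s.utility, [("state", i, "utility")], 1.0)
        )

    st = model.settings
    if st.followup_cost_year1 > 0:
        params.append(
            Parameter("cost.followup_year1", "cost", st.followup_cost_year1,
                      [("settings", None, "followup_cost_year1")])
        )
    if st.followup_cost_later > 0:
        params.append(
            Parameter("cost.followup_later", "cost", st.followup_cost_later,
                      [("settings", None, "followup_cost_later")])
        )
    if st.admission_cost > 0:
        params.append(
            Parameter("cost.admission", "cost", st.admission_cost,
                      [("settings", None, "admission_cost")])
        )
    for i, a in enumerate(model.strategies):
        if not a.fee_fixed and a.treatment_fee > 0:
            params.append(
                Parameter(f"cost.fee.{a.id}", "cost", a.treatment_fee,
                          [("strategy", i, "treatment_fee")])
            )
    for i, s in enumerate(model.states):
        if s.extra_cycle_cost > 0:
            params.append(
                Parameter(f"cost.cycle.{s.id}", "cost", s.extra_cycle_cost,
                          [("state", i, "extra_cycle_cost")])
            )
        if s.entry_cost > 0:
            params.append(
                Parameter(f"cost.entry.{s.id}", "cost", s.entry_cost,
                          [("state", i, "entry_cost")])
            )
        if s.followup == "override":
            for attr in ("followup_override_year1", "followup_override_later"):
                params.append(
                    Parameter(f"cost.{attr}.{s.id}", "cost", getattr(s, attr),
                              [("state", i, attr)])
                )

    seen: dict[str, int] = {}
    for i, r in enumerate(model.rules):
        if r.probability is None or not r.perturbable:
            continue  # structural rule
        pid = f"prob.{r.strategy}.{r.from_state}>{r.to_state}"
        if pid in seen:
            seen[pid] += 1
            pid = f"{pid}#{seen[pid]}"
        else:
            seen[pid] = 0
        params.append(
            Parameter(pid, "probability", r.probability, [("rule", i, "probability")], 1.0)
        )

    return _merge_links(params, model.param_links)


def _merge_links(params: list[Parameter], links: list[list[str]]) -> list[Parameter]:
    by_id = {p.id: p for p in params}
    merged: set[str] = set()
    for group in links:
        members = [by_id[pid] for pid in group if pid in by_id]
        if len(members) < 2:
            continue
        head = members[0]
        bases = {m.base for m in members}
        if len(bases) != 1:
            raise ValueError(
                f"linked parameters {group} have differing base values {sorted(bases)}"
            )
        head.targets = [t for m in members for t in m.targets]
        head.linked_ids = tuple(m.id for m in members)
        merged.update(m.id for m in members[1:])
    return [p for p in params if p.id not in merged]


@dataclass
class DrawFlags:
    """Constraint-handling events during one probabilistic draw."""

    utility_sort_fallback: list[str] = field(default_factory=list)
    row_rescale_fallback: list[str] = field(default_factory=list)

    @property
    def any(self) -> bool:
        return bool(self.utility_sort_fallback or self.row_rescale_fallback)


def _draw_value(rng: np.random.Generator, base: float, width: float, clamp_high) -> float:
    lo, hi = base * (1 - width), base * (1 + width)
    if base == 0.0 or lo == hi:  # zero base or support below float resolution
        return base
    v = float(rng.triangular(lo, base, hi))
    if clamp_high is not None:
        v = min(v, clamp_high)
    return v


def _row_groups(model: ModelDefinition):
    """Literal-rule indices grouped by (strategy, source state).

    Used to check that no outgoing probability row exceeds 1 at any cycle;
    row sums are piecewise constant in the cycle, so it suffices to check
    at each rule's window start (clipped to the horizon).
    """
    groups: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(model.rules):
        if r.probability is None:
            continue
        for strategy in ([a.id for a in model.strategies] if r.strategy == "shared" else [r.strategy]):
            for src in model.expand_sources(r):
                groups.setdefault((strategy, src), []).append(i)
    return groups


def _row_violations(model: ModelDefinition, groups) -> list[tuple[str, str]]:
    horizon = model.settings.horizon_cycles
    bad = []
    for (strategy, src), idxs in groups.items():
        rules = [model.rules[i] for i in idxs]
        checkpoints = {min(r.window_start, horizon) for r in rules}
        for c in checkpoints:
            total = sum(
                r.probability
                for r in rules
                if r.window_start <= c <= (r.window_end if r.window_end is not None else horizon)
            )
            if total > 1.0 + 1e-12:
                bad.append((strategy, src))
                break
    return bad


def sample_draw(
    model: ModelDefinition,
    rng: np.random.Generator,
    width: float = 0.2,
    max_retries: int = 100,
) -> tuple[ModelDefinition, DrawFlags]:
    """One probabilistic-sensitivity draw of a model.

    Returns a new, valid :class:`ModelDefinition` whose perturbable
    scalars are each drawn from a triangular distribution centred on
    their base value with support ``±width`` (relative), plus flags
    recording any deterministic constraint fallback.  ``width=0`` returns
    an identical copy.
    """
    out = copy_model(model)
    flags = DrawFlags()
    if width == 0.0:
        return out, flags

    params = enumerate_parameters(out)
    for p in params:
        p.set(out, _draw_value(rng, p.base, width, p.clamp_high))

    # Utility grade ordering within each declared adverse-event family:
    # redraw the violating family, fall back to sorting its drawn values.
    util_by_state = {
        p.targets[0][1]: p for p in params if p.kind == "utility"
    }
    for chain in out.utility_orderings:
        idxs = [out.state_index(sid) for sid in chain]
        chain_params = [util_by_state[i] for i in idxs if i in util_by_state]
        if len(chain_params) < 2:
            continue
        for _ in range(max_retries):
            vals = [p.get(out) for p in chain_params]
            if all(a >= b - 1e-12 for a, b in zip(vals, vals[1:])):
                break
            for p in chain_params:
                p.set(out, _draw_value(rng, p.base, width, p.clamp_high))
        else:
            vals = sorted((p.get(out) for p in chain_params), reverse=True)
            for p, v in zip(chain_params, vals):
                p.set(out, v)
            flags.utility_sort_fallback.extend(chain)

    # Outgoing probability rows must not exceed 1 at any cycle: redraw the
    # offending rows' probability parameters, fall back to proportional
    # rescaling of the drawn values.
    groups = _row_groups(out)
    prob_by_rule = {
        t[1]: p for p in params if p.kind == "probability" for t in p.targets
    }
    for _ in range(max_retries):
        bad = _row_violations(out, groups)
        if not bad:
            break
        redraw = {
            prob_by_rule[i].id: prob_by_rule[i]
            for strategy, src in bad
            for i in groups[(strategy, src)]
            if i in prob_by_rule
        }
        for p in redraw.values():
            p.set(out, _draw_value(rng, p.base, width, p.clamp_high))
    else:
        for strategy, src in _row_violations(out, groups):
            idxs = groups[(strategy, src)]
            horizon = out.settings.horizon_cycles
            worst = max(
                sum(
                    r.probability
                    for r in (out.rules[i] for i in idxs)
                    if r.window_start <= c <= (r.window_end if r.window_end is not None else horizon)
                )
                for c in {min(out.rules[i].window_start, horizon) for i in idxs}
            )
            scale = (1.0 - 1e-9) / worst
            for i in idxs:
                out.rules[i].probability *= scale
            flags.row_rescale_fallback.append(f"{strategy}:{src}")

    return out, flags
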