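"""Markov cohort engine: transition matrices, cohort traces, outcomes.

The cohort starts with all mass in the start state (stage 0) and is
propagated through ``horizon_cycles`` transitions.  Rewards follow the
convention of cohort decision-analysis software: the cohort occupying a
state at the *beginning* of cycle ``k`` (0-based stage index ``k``)
accrues that state's utility and per-cycle cost for the cycle, discounted
by ``(1 + r)^(-k * cycle_length / 12)``; one-off entry costs are charged
to the fraction of the cohort entering a state at stage ``k`` with the
same stage-``k`` discount factor.  Mass still alive after the final
transition simply stops accruing (horizon truncation).  An optional
half-cycle correction replaces each cycle's occupancy with the average of
its start- and end-of-cycle occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelDefinition, validate

__all__ = [
    "TransitionMatrix",
    "CohortTrace",
    "StrategyOutcome",
    "build_matrix",
    "run_cohort",
    "accumulate",
    "run_strategy",
]


@dataclass
class TransitionMatrix:
    """Per-cycle transition probabilities for one arm, row-stochastic."""

    cycle: int
    strategy: str
    state_ids: list[str]
    entries: np.ndarray  # (S, S), rows sum to 1

    def row(self, state_id: str) -> np.ndarray:
        return self.entries[self.state_ids.index(state_id)]


@dataclass
class CohortTrace:
    """State occupancy and inflow of one arm's cohort over the horizon.

    ``occupancy[k]`` is the distribution at stage ``k`` (after ``k``
    transitions); ``occupancy[0]`` puts mass 1 on the start state.
    ``inflow[k, s]`` is the cohort fraction *entering* state ``s`` at
    transition ``k`` from a different state (basis for entry costs).
    """

    strategy: str
    state_ids: list[str]
    occupancy: np.ndarray  # (H+1, S)
    inflow: np.ndarray  # (H+1, S); row 0 is zero

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(cycle, state) table: occupancy and inflow."""
        h, s = self.occupancy.shape
        return pd.DataFrame(
            {
                "cycle": np.repeat(np.arange(h), s),
                "state": np.tile(self.state_ids, h),
                "occupancy": self.occupancy.ravel(),
                "inflow": self.inflow.ravel(),
            }
        )


@dataclass
class StrategyOutcome:
    """Discounted totals for one arm."""

    strategy: str
    total_cost: float
    total_qaly: float
    undiscounted_ly: float
    per_state_cost_breakdown: dict[str, float] = field(default_factory=dict)


def build_matrix(model: ModelDefinition, strategy: str, cycle: int) -> TransitionMatrix:
    """Transition matrix for one arm and cycle (1-based cycle index).

    Applies exactly the rules whose window contains ``cycle``; the
    implicit stay probability is the complement of the explicit outgoing
    mass.  A remainder rule absorbs that complement instead.  Raises
    ``ValueError`` if literal rules overcommit a row (negative stay).
    """
    if not 1 <= cycle <= model.settings.horizon_cycles:
        raise ValueError(f"cycle {cycle} outside 1..{model.settings.horizon_cycles}")
    ids = [s.id for s in model.states]
    n = len(ids)
    mat = np.zeros((n, n))
    for i, state in enumerate(model.states):
        if state.is_absorbing:
            mat[i, i] = 1.0
            continue
        rules = model.rules_from(strategy, state.id, cycle)
        literal = 0.0
        remainder_rule = None
        for r in rules:
            if r.probability is None:
                if remainder_rule is not None:
                    raise ValueError(
                        f"state {state.id}: multiple remainder rules at cycle {cycle}"
                    )
                remainder_rule = r
            else:
                mat[i, ids.index(r.to_state)] += r.probability
                literal += r.probability
        stay = 1.0 - literal
        if stay < -1e-12:
            raise ValueError(
                f"state {state.id} ({strategy}): outgoing probabilities sum to "
                f"{literal:.6g} > 1 at cycle {cycle}"
            )
        stay = max(stay, 0.0)
        if remainder_rule is not None:
            mat[i, ids.index(remainder_rule.to_state)] += stay
        else:
            mat[i, i] += stay
    return TransitionMatrix(cycle=cycle, strategy=strategy, state_ids=ids, entries=mat)


def run_cohort(model: ModelDefinition, strategy: str, check: bool = True) -> CohortTrace:
    """Propagate the cohort over the full horizon for one arm."""
    if check:
        problems = validate(model)
        if problems:
            raise ValueError("invalid model: " + "; ".join(problems))
    ids = [s.id for s in model.states]
    horizon = model.settings.horizon_cycles
    occ = np.zeros((horizon + 1, len(ids)))
    inflow = np.zeros_like(occ)
    occ[0, model.state_index(model.start_state)] = 1.0
    for t in range(1, horizon + 1):
        m = build_matrix(model, strategy, t).entries
        occ[t] = occ[t - 1] @ m
        # entries = arrivals from *other* states (stayers are not re-entries)
        inflow[t] = occ[t] - occ[t - 1] * np.diag(m)
    return CohortTrace(strategy=strategy, state_ids=ids, occupancy=occ, inflow=inflow)


def _cycle_cost_matrix(model: ModelDefinition) -> np.ndarray:
    """Per-cycle cost of each state for each stage k=0..H-1, shape (H, S)."""
    st = model.settings
    horizon = st.horizon_cycles
    y1 = st.year1_cycles
    costs = np.zeros((horizon, len(model.states)))
    for j, s in enumerate(model.states):
        for k in range(horizon):
            first_year = k < y1
            if s.followup == "standard":
                base = st.followup_cost_year1 if first_year else st.followup_cost_later
            elif s.followup == "override":
                base = (
                    s.followup_override_year1 if first_year else s.followup_override_later
                )
            else:
                base = 0.0
            if k == 0 and not st.followup_in_first_cycle and s.followup != "none":
                base = 0.0  # treatment admission covers the first cycle
            costs[k, j] = base + s.extra_cycle_cost
    return costs


def accumulate(model: ModelDefinition, trace: CohortTrace) -> StrategyOutcome:
    """Discounted cost and QALY totals for a cohort trace.

    QALYs accrue as ``utility * cycle_length/12`` per cycle of occupancy;
    costs as upfront (stage 0, undiscounted) + per-cycle state costs +
    one-off entry costs on inflow.
    """
    if trace.state_ids != [s.id for s in model.states]:
        raise ValueError("trace does not match model (state sets differ)")
    st = model.settings
    horizon = st.horizon_cycles
    if trace.occupancy.shape[0] != horizon + 1:
        raise ValueError("trace does not match model (horizon differs)")

    disc = np.array([st.discount_factor(k) for k in range(horizon + 1)])
    util = np.array([s.utility for s in model.states])
    entry = np.array([s.entry_cost for s in model.states])
    alive = np.array([0.0 if s.id == "death" else 1.0 for s in model.states])
    cycle_frac = st.cycle_length_months / 12.0
    cc = _cycle_cost_matrix(model)  # (H, S)

    occ_cycle = trace.occupancy[:horizon]  # start-of-cycle occupancy
    if st.half_cycle_correction:
        occ_cycle = 0.5 * (trace.occupancy[:horizon] + trace.occupancy[1:])

    w = disc[:horizon, None] * occ_cycle  # (H, S) discounted occupancy
    qaly = float(np.sum(w @ util) * cycle_frac)
    ly = float(np.sum(trace.occupancy[:horizon] @ alive) * cycle_frac)

    per_state = (w * cc).sum(axis=0)  # discounted per-cycle costs by state
    entry_by_state = (disc[1:, None] * trace.inflow[1:]).sum(axis=0) * entry
    upfront = model.upfront_cost(trace.strategy)

    breakdown = {"upfront": upfront}
    for j, s in enumerate(model.states):
        v = float(per_state[j] + entry_by_state[j])
        if v:
            breakdown[s.id] = v
    total_cost = upfront + float(per_state.sum() + entry_by_state.sum())
    return StrategyOutcome(
        strategy=trace.strategy,
        total_cost=total_cost,
        total_qaly=qaly,
        undiscounted_ly=ly,
        per_state_cost_breakdown=breakdown,
    )


def run_strategy(model: ModelDefinition, strategy: str, check: bool = True) -> StrategyOutcome:
    """Convenience: trace + accumulate for one arm."""
    return accumulate(model, run_cohort(model, strategy, check=check))
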