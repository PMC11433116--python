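"""Individual-level (first-order Monte Carlo) simulation oracle.

Samples whole patient trajectories from the same per-cycle transition
matrices the cohort engine uses, accruing discounted costs and QALYs per
patient with the same conventions, and reports means with Monte Carlo
standard errors.  By the law of large numbers these converge to the
cohort engine's expectations, which makes this module an independent
cross-check of the cohort propagation and accrual code: apart from
:func:`markovcua.engine.build_matrix` (whose matrices are the object
under test's own input) no code is shared with the cohort engine — cost
phases, discounting and entry detection are re-derived here along a
row-sampling path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import build_matrix
from .model import ModelDefinition, validate

__all__ = ["MicrosimResult", "simulate_patients"]


@dataclass
class MicrosimResult:
    strategy: str
    n: int
    seed: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    state_ids: list[str]
    occupancy: np.ndarray  # (H+1, S) fraction of patients per stage


def _state_cycle_costs(model: ModelDefinition) -> np.ndarray:
    """Per-cycle cost of each state at each stage, derived independently
    of the cohort engine's cost matrix."""
    st = model.settings
    year1 = int(round(12.0 / st.cycle_length_months))
    out = np.zeros((st.horizon_cycles, len(model.states)))
    for j, s in enumerate(model.states):
        for k in range(st.horizon_cycles):
            if s.followup == "standard":
                fu = st.followup_cost_year1 if k < year1 else st.followup_cost_later
            elif s.followup == "override":
                fu = s.followup_override_year1 if k < year1 else s.followup_override_later
            else:
                fu = 0.0
            if k == 0 and not st.followup_in_first_cycle:
                fu = 0.0
            out[k, j] = fu + s.extra_cycle_cost
    return out


def simulate_patients(
    model: ModelDefinition,
    strategy: str,
    n: int,
    seed: int = 0,
) -> MicrosimResult:
    """Simulate ``n`` independent patients through one arm.

    All patients start in the start state; each cycle, the next state is
    drawn from the applicable transition-matrix row.  Entry costs are
    charged whenever a patient arrives in a state it did not occupy the
    previous cycle.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    problems = validate(model)
    if problems:
        raise ValueError("invalid model: " + "; ".join(problems))

    st = model.settings
    horizon = st.horizon_cycles
    states = model.states
    n_states = len(states)
    rng = np.random.default_rng(seed)

    util = np.array([s.utility for s in states])
    entry = np.array([s.entry_cost for s in states])
    cc = _state_cycle_costs(model)
    cycle_frac = st.cycle_length_months / 12.0
    rate = 1.0 + st.annual_discount_rate
    disc = rate ** (-np.arange(horizon + 1) * cycle_frac)
    hcc = st.half_cycle_correction

    state = np.full(n, model.state_index(model.start_state), dtype=np.intp)
    cost = np.full(n, model.upfront_cost(strategy))
    qaly = np.zeros(n)
    occupancy = np.zeros((horizon + 1, n_states))
    occupancy[0] = np.bincount(state, minlength=n_states) / n

    for t in range(1, horizon + 1):
        k = t - 1  # stage being lived through this cycle
        w = 0.5 if hcc else 1.0
        cost += w * cc[k, state] * disc[k]
        qaly += w * util[state] * cycle_frac * disc[k]

        cum = np.cumsum(build_matrix(model, strategy, t).entries, axis=1)
        cum[:, -1] = 1.0  # guard against cumulative rounding
        u = rng.random(n)
        new_state = (u[:, None] > cum[state]).sum(axis=1).astype(np.intp)

        moved = new_state != state
        cost += entry[new_state] * disc[t] * moved
        if hcc:
            cost += 0.5 * cc[k, new_state] * disc[k]
            qaly += 0.5 * util[new_state] * cycle_frac * disc[k]
        state = new_state
        occupancy[t] = np.bincount(state, minlength=n_states) / n

    return MicrosimResult(
        strategy=strategy,
        n=n,
        seed=seed,
        mean_cost=float(cost.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_qaly=float(qaly.mean()),
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        state_ids=[s.id for s in states],
        occupancy=occupancy,
    )
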