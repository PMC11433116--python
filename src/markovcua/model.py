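"""Model definition types for a Markov cohort cost-utility analysis.

A :class:`ModelDefinition` describes a discrete-time state-transition
(Markov cohort) model used to compare two treatment strategies: a set of
health states with utility weights and costs, time-windowed per-cycle
transition rules, two strategy arms differing in upfront treatment fee
(and possibly in transition probabilities), and global settings (cycle
length, horizon, discount rate, willingness-to-pay threshold).

Costs follow the conventions of Japanese social-insurance fee schedules:
everything is in yen, an upfront radiotherapy + admission/chemotherapy
cost is charged at time zero, routine follow-up accrues per cycle at a
first-year and a later rate, and severe adverse events carry one-off
hospitalization costs charged on state entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "HealthState",
    "TransitionRule",
    "StrategyDefinition",
    "ModelSettings",
    "ModelDefinition",
    "ANY_ALIVE",
    "validate",
]

#: Wildcard source for rules that apply from every alive, non-terminal-care
#: state (e.g. a shared per-cycle hazard of moving to best supportive care).
ANY_ALIVE = "*"

FOLLOWUP_MODES = ("standard", "override", "none")


@dataclass
class HealthState:
    """One Markov health state.

    Parameters
    ----------
    utility
        Preference weight in [0, 1] multiplied by time spent in the state.
    extra_cycle_cost
        Yen accrued each cycle in the state *in addition to* routine
        follow-up (e.g. ongoing Grade 2 pneumonitis medication).
    entry_cost
        Yen accrued once per entry into the state (hospitalization episodes).
    followup
        ``"standard"``: the model-wide follow-up cost accrues each cycle;
        ``"override"``: the state's own ``followup_override_*`` costs
        replace it (states whose published treatment cost already includes
        the follow-up fee); ``"none"``: no routine follow-up (terminal
        care, death).
    """

    id: str
    label: str = ""
    utility: float = 0.0
    extra_cycle_cost: float = 0.0
    entry_cost: float = 0.0
    followup: str = "standard"
    followup_override_year1: float | None = None
    followup_override_later: float | None = None
    is_absorbing: bool = False
    is_terminal_care: bool = False


@dataclass
class TransitionRule:
    """A per-cycle transition probability, active on a cycle window.

    ``probability=None`` marks a *remainder* rule: it absorbs whatever
    probability mass is left after all literal rules from the same state,
    instead of the implicit "stay" self-transition.  Remainder rules are
    structural (forced one-cycle moves such as tunnel-state exits) and are
    never perturbed by sensitivity analyses.
    """

    strategy: str  # arm id or "shared"
    from_state: str  # state id or ANY_ALIVE
    to_state: str
    probability: float | None
    window_start: int = 1
    window_end: int | None = None  # inclusive; None = open-ended
    #: structural probabilities (fee-schedule analogues of fixed fees, the
    #: shared survival hazard under an equal-survival assumption) can be
    #: excluded from sensitivity analyses
    perturbable: bool = True

    def applies(self, strategy_id: str, cycle: int) -> bool:
        if self.strategy not in ("shared", strategy_id):
            return False
        if cycle < self.window_start:
            return False
        return self.window_end is None or cycle <= self.window_end


@dataclass
class StrategyDefinition:
    """One treatment arm: identity and its upfront radiotherapy fee.

    The total time-zero cost of an arm is ``treatment_fee`` plus the
    model-wide admission/chemotherapy cost (shared between arms).
    ``fee_fixed`` marks scenario-defining fees that sensitivity analyses
    must not vary.
    """

    id: str
    treatment_fee: float
    fee_fixed: bool = False


@dataclass
class ModelSettings:
    cycle_length_months: float = 3.0
    horizon_cycles: int = 20
    annual_discount_rate: float = 0.03
    wtp_threshold: float = 7_500_000.0
    half_cycle_correction: bool = False
    followup_cost_year1: float = 0.0
    followup_cost_later: float = 0.0
    admission_cost: float = 0.0
    #: whether routine follow-up accrues during the first cycle (stage 0).
    #: Off by default: the first cycle is the chemoradiotherapy admission,
    #: whose costs are already in the upfront admission figure.
    followup_in_first_cycle: bool = False

    @property
    def cycles_per_year(self) -> float:
        return 12.0 / self.cycle_length_months

    @property
    def year1_cycles(self) -> int:
        """Number of cycles that make up the first year (cost phase 1)."""
        return int(round(self.cycles_per_year))

    def discount_factor(self, stage: float) -> float:
        """Discount factor for stage ``stage`` (0-based cycle index)."""
        years = stage * self.cycle_length_months / 12.0
        return (1.0 + self.annual_discount_rate) ** (-years)


@dataclass
class ModelDefinition:
    """A complete two-arm Markov cohort model ready for simulation."""

    states: list[HealthState]
    rules: list[TransitionRule]
    strategies: list[StrategyDefinition]
    settings: ModelSettings
    start_state: str
    #: ordered chains of state ids whose utilities must be non-increasing
    #: (severity grading within an adverse-event family)
    utility_orderings: list[list[str]] = field(default_factory=list)
    #: groups of parameter ids perturbed jointly by sensitivity analyses
    param_links: list[list[str]] = field(default_factory=list)

    def state(self, state_id: str) -> HealthState:
        for s in self.states:
            if s.id == state_id:
                return s
        raise KeyError(f"unknown state {state_id!r}")

    def state_index(self, state_id: str) -> int:
        for i, s in enumerate(self.states):
            if s.id == state_id:
                return i
        raise KeyError(f"unknown state {state_id!r}")

    def strategy(self, strategy_id: str) -> StrategyDefinition:
        for a in self.strategies:
            if a.id == strategy_id:
                return a
        raise KeyError(f"unknown strategy {strategy_id!r}")

    def upfront_cost(self, strategy_id: str) -> float:
        """Time-zero cost of an arm: treatment fee + admission/chemo."""
        return self.strategy(strategy_id).treatment_fee + self.settings.admission_cost

    def expand_sources(self, rule: TransitionRule) -> list[str]:
        """State ids a rule fires from (resolves the ANY_ALIVE wildcard)."""
        if rule.from_state != ANY_ALIVE:
            return [rule.from_state]
        return [
            s.id
            for s in self.states
            if not s.is_absorbing and not s.is_terminal_care
        ]

    def rules_from(self, strategy_id: str, state_id: str, cycle: int) -> list[TransitionRule]:
        """Rules applicable from ``state_id`` at ``cycle`` for an arm."""
        out = []
        for r in self.rules:
            if not r.applies(strategy_id, cycle):
                continue
            if r.from_state == state_id or (
                r.from_state == ANY_ALIVE and state_id in self.expand_sources(r)
            ):
                out.append(r)
        return out


def _check_state(s: HealthState, out: list[str]) -> None:
    if not (0.0 <= s.utility <= 1.0):
        out.append(f"state {s.id}: utility {s.utility} outside [0, 1]")
    if s.extra_cycle_cost < 0:
        out.append(f"state {s.id}: negative per-cycle cost")
    if s.entry_cost < 0:
        out.append(f"state {s.id}: negative entry cost")
    if s.followup not in FOLLOWUP_MODES:
        out.append(f"state {s.id}: unknown followup mode {s.followup!r}")
    if s.followup == "override":
        for name in ("followup_override_year1", "followup_override_later"):
            v = getattr(s, name)
            if v is None or v < 0:
                out.append(f"state {s.id}: invalid {name} {v!r}")


def validate(model: ModelDefinition) -> list[str]:
    """Check every structural invariant; return violation descriptions.

    An empty list means the model is simulable.  Violations are data, not
    exceptions, so callers (e.g. constraint-respecting samplers) can react
    to individual problems.
    """
    out: list[str] = []
    ids = [s.id for s in model.states]
    if len(set(ids)) != len(ids):
        out.append("duplicate state ids")

    for s in model.states:
        _check_state(s, out)

    death = [s for s in model.states if s.id == "death"]
    if len(death) != 1:
        out.append("model must declare exactly one state with id 'death'")
    else:
        d = death[0]
        if not d.is_absorbing or d.utility != 0 or d.entry_cost != 0 or d.extra_cycle_cost != 0:
            out.append("death must be absorbing with zero utility and zero costs")
    terminal = [s for s in model.states if s.is_terminal_care]
    if len(terminal) != 1:
        out.append("model must declare exactly one terminal-care state")

    if model.start_state not in ids:
        out.append(f"start_state {model.start_state!r} not declared")

    if len(model.strategies) != 2:
        out.append("model must declare exactly two strategies")
    for a in model.strategies:
        if a.treatment_fee + model.settings.admission_cost < 0:
            out.append(f"strategy {a.id}: negative upfront cost")

    st = model.settings
    if not (0.0 <= st.annual_discount_rate < 1.0):
        out.append("annual_discount_rate outside [0, 1)")
    if st.horizon_cycles < 1 or st.cycle_length_months <= 0:
        out.append("horizon_cycles and cycle_length_months must be positive")
    if st.followup_cost_year1 < 0 or st.followup_cost_later < 0 or st.admission_cost < 0:
        out.append("negative settings cost")

    strategy_ids = [a.id for a in model.strategies]
    for r in model.rules:
        if r.strategy not in strategy_ids + ["shared"]:
            out.append(f"rule {r.from_state}->{r.to_state}: unknown strategy {r.strategy!r}")
        for ref in (r.from_state, r.to_state):
            if ref != ANY_ALIVE and ref not in ids:
                out.append(f"rule {r.from_state}->{r.to_state}: unknown state {ref!r}")
        if r.to_state == ANY_ALIVE:
            out.append(f"rule {r.from_state}->{r.to_state}: wildcard target not allowed")
        if r.probability is not None and not (0.0 <= r.probability <= 1.0):
            out.append(
                f"rule {r.from_state}->{r.to_state} ({r.strategy}): "
                f"probability {r.probability} outside [0, 1]"
            )
        if r.window_start < 1:
            out.append(f"rule {r.from_state}->{r.to_state}: window_start < 1")
        if r.window_end is not None and r.window_end < r.window_start:
            out.append(f"rule {r.from_state}->{r.to_state}: empty window")
        if r.from_state in ids and model.state(r.from_state).is_absorbing:
            out.append(f"rule {r.from_state}->{r.to_state}: transition out of absorbing state")

    if out:
        return out  # structure broken; skip numeric row checks

    # Row sums and remainder uniqueness, per strategy and cycle.
    for strategy in strategy_ids:
        for s in model.states:
            if s.is_absorbing:
                continue
            for cycle in range(1, st.horizon_cycles + 1):
                rules = model.rules_from(strategy, s.id, cycle)
                literal = sum(r.probability for r in rules if r.probability is not None)
                n_rem = sum(1 for r in rules if r.probability is None)
                if n_rem > 1:
                    out.append(
                        f"state {s.id} ({strategy}, cycle {cycle}): "
                        "multiple remainder rules"
                    )
                if literal > 1.0 + 1e-9:
                    out.append(
                        f"state {s.id} ({strategy}, cycle {cycle}): "
                        f"outgoing row sum {literal:.6g} > 1"
                    )

    # Utility grade ordering within each declared adverse-event family.
    for chain in model.utility_orderings:
        for hi, lo in zip(chain, chain[1:]):
            if model.state(hi).utility < model.state(lo).utility - 1e-12:
                out.append(
                    f"utility ordering violated: {hi} ({model.state(hi).utility}) "
                    f"< {lo} ({model.state(lo).utility})"
                )

    # Death must be reachable from the start state in each arm.
    for strategy in strategy_ids:
        reach = {model.start_state}
        frontier = [model.start_state]
        while frontier:
            cur = frontier.pop()
            for r in model.rules:
                if r.strategy not in ("shared", strategy):
                    continue
                sources = model.expand_sources(r)
                if cur in sources and (r.probability is None or r.probability > 0):
                    if r.to_state not in reach:
                        reach.add(r.to_state)
                        frontier.append(r.to_state)
        if "death" not in reach:
            out.append(f"strategy {strategy}: no path from start_state to death")

    return out


def is_valid(model: ModelDefinition) -> bool:
    return not validate(model)


def copy_model(model: ModelDefinition) -> ModelDefinition:
    """Deep, independent copy (sensitivity analyses mutate copies)."""
    return ModelDefinition(
        states=[replace(s) for s in model.states],
        rules=[replace(r) for r in model.rules],
        strategies=[replace(a) for a in model.strategies],
        settings=replace(model.settings),
        start_state=model.start_state,
        utility_orderings=[list(c) for c in model.utility_orderings],
        param_links=[list(g) for g in model.param_links],
    )
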