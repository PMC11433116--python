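"""Incremental cost-effectiveness comparison of two strategy outcomes."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .engine import StrategyOutcome, run_strategy
from .model import ModelDefinition, copy_model
from .packaged import packaged_model

__all__ = ["CEAResult", "BaseCaseResult", "compare", "run_model", "run_base_case", "convention_sweep"]


@dataclass
class CEAResult:
    """Incremental comparison of ``comparator`` against ``reference``.

    ``icer`` is yen per QALY from *unrounded* deltas; ``None`` when
    ``delta_qaly`` is zero.  ``dominance`` classifies the incremental
    quadrant: ``dominant`` (cheaper, at least as effective), ``dominated``
    (the mirror), ``tradeoff-NE`` (costlier and more effective) or
    ``tradeoff-SW`` (cheaper and less effective).
    """

    comparator: str
    reference: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    nmb_at_wtp: float
    wtp: float
    dominance: str

    @property
    def cost_effective(self) -> bool:
        """Threshold verdict: positive health gain at ICER <= WTP, or dominant."""
        return self.nmb_at_wtp > 0 if self.delta_qaly != 0 else self.delta_cost < 0


def _dominance(dc: float, de: float) -> str:
    if dc <= 0 and de >= 0 and (dc != 0 or de != 0):
        return "dominant"
    if dc >= 0 and de <= 0 and (dc != 0 or de != 0):
        return "dominated"
    return "tradeoff-NE" if de > 0 else "tradeoff-SW"


def compare(
    comparator: StrategyOutcome, reference: StrategyOutcome, wtp: float
) -> CEAResult:
    """Incremental cost, effectiveness, ICER and net monetary benefit."""
    dc = comparator.total_cost - reference.total_cost
    de = comparator.total_qaly - reference.total_qaly
    icer = dc / de if de != 0 else None
    return CEAResult(
        comparator=comparator.strategy,
        reference=reference.strategy,
        delta_cost=dc,
        delta_qaly=de,
        icer=icer,
        nmb_at_wtp=wtp * de - dc,
        wtp=wtp,
        dominance=_dominance(dc, de),
    )


@dataclass
class BaseCaseResult:
    """Both arms' outcomes plus their incremental comparison."""

    comparator: StrategyOutcome
    reference: StrategyOutcome
    cea: CEAResult

    @property
    def verdict(self) -> str:
        return "cost-effective" if self.cea.cost_effective else "not cost-effective"


def run_model(
    model: ModelDefinition,
    comparator: str = "PBT",
    reference: str = "3DCRT",
    check: bool = True,
) -> BaseCaseResult:
    """End-to-end deterministic evaluation of a two-arm model."""
    out_c = run_strategy(model, comparator, check=check)
    out_r = run_strategy(model, reference, check=check)
    return BaseCaseResult(out_c, out_r, compare(out_c, out_r, model.settings.wtp_threshold))


def run_base_case(fee_level: str = "rare") -> BaseCaseResult:
    """Evaluate the packaged model at one of the two PBT fee levels."""
    return run_model(packaged_model(fee_level))


def convention_sweep(fee_level: str = "rare") -> "pd.DataFrame":
    """Re-run the base case under alternative accrual conventions.

    The original analysis was built in commercial decision-tree software
    whose half-cycle handling and cost-attachment points are not fully
    published.  This sweep toggles the genuinely ambiguous conventions —
    half-cycle correction on/off, Grade 2 pneumonitis treatment cost
    stacked on top of routine follow-up vs replacing it, the (unpublished)
    utility assigned to the drainage and pericardiotomy tunnel states, the
    reading of the Grade 2 pneumonitis persistence row (literal
    self-transition 0.25 vs an improvement probability of 0.25), and
    whether routine follow-up accrues during the treatment cycle — and
    reports the resulting base-case quantities so the sensitivity of the
    reproduction to each choice is visible.
    """
    import itertools

    import pandas as pd

    rows = []
    grid = itertools.product(
        (False, True),  # half-cycle correction
        (True, False),  # RP G2 cost stacked on follow-up
        (0.63, 0.57, 0.32),  # tunnel-state utility
        ("literal", "recovery"),  # RP G2 persistence row reading
        (False, True),  # follow-up during treatment cycle
    )
    for half_cycle, rp_stacking, tunnel_utility, rp_g2_reading, fu0 in grid:
        model = copy_model(packaged_model(fee_level))
        model.settings.half_cycle_correction = half_cycle
        model.settings.followup_in_first_cycle = fu0
        if not rp_stacking:
            # read the published Grade 2 RP cost as *including* follow-up
            s = model.state("rp_g2")
            s.followup = "override"
            s.followup_override_year1 = s.extra_cycle_cost
            s.followup_override_later = s.extra_cycle_cost
            s.extra_cycle_cost = 0.0
        if rp_g2_reading == "recovery":
            # 0.25 read as the improvement probability G2 -> G1
            for r in model.rules:
                if r.from_state == "rp_g2" and r.to_state == "rp_g2":
                    model.rules.remove(r)
                    break
            for r in model.rules:
                if r.from_state == "rp_g2" and r.to_state == "rp_g1":
                    r.probability = 0.25
        for sid in ("drainage", "pericardiotomy"):
            model.state(sid).utility = tunnel_utility
        res = run_model(model)
        rows.append(
            {
                "half_cycle_correction": half_cycle,
                "rp_cost_stacking": rp_stacking,
                "tunnel_utility": tunnel_utility,
                "rp_g2_reading": rp_g2_reading,
                "followup_in_first_cycle": fu0,
                "cost_comparator": res.comparator.total_cost,
                "cost_reference": res.reference.total_cost,
                "qaly_comparator": res.comparator.total_qaly,
                "qaly_reference": res.reference.total_qaly,
                "delta_cost": res.cea.delta_cost,
                "delta_qaly": res.cea.delta_qaly,
                "icer": res.cea.icer,
            }
        )
    return pd.DataFrame(rows)
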