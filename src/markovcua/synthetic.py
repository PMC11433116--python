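"""Random valid model generation for pipeline testing.

:func:`random_model` emits structurally faithful but randomly
parameterized two-arm models — a start state, graded adverse-event
families with monotone utilities, an optional one-cycle tunnel state, a
shared per-cycle terminal-care hazard and window-limited onset rules —
so every analysis stage can be exercised without the packaged defaults.
Emitted models always pass :func:`markovcua.model.validate` and
round-trip through the configuration reader/writer.
"""

from __future__ import annotations

import numpy as np

from .model import (
    ANY_ALIVE,
    HealthState,
    ModelDefinition,
    ModelSettings,
    StrategyDefinition,
    TransitionRule,
    validate,
)
from .params import sample_draw

__all__ = ["random_model", "perturb_model"]

#: beyond this many adverse-event states the onset row from the start
#: state cannot stay meaningfully below 1 at the generator's minimum
#: onset probability
MAX_AE_STATES = 40


def random_model(
    seed: int = 0,
    n_ae_states: int = 6,
    horizon: int = 20,
    onset_window: int = 4,
    with_tunnel: bool = True,
) -> ModelDefinition:
    """Generate a random, valid two-arm Markov cost-utility model.

    Parameters
    ----------
    n_ae_states
        Total number of graded adverse-event states (grouped into
        families of up to three grades with utilities decreasing in
        grade).  ``0`` yields the minimal start → terminal-care → death
        model whose discounted QALY total has a geometric closed form.
    onset_window
        Last cycle (inclusive) at which adverse-event onset from the
        start state can occur.
    """
    if n_ae_states < 0:
        raise ValueError("n_ae_states must be >= 0")
    if n_ae_states > MAX_AE_STATES:
        raise ValueError(
            f"n_ae_states={n_ae_states} is infeasible: the onset row from the "
            f"start state cannot stay below 1 (max {MAX_AE_STATES})"
        )
    if horizon < 1 or onset_window < 1:
        raise ValueError("horizon and onset_window must be >= 1")

    rng = np.random.default_rng(seed)
    u_start = float(rng.uniform(0.85, 0.95))
    hazard = float(rng.uniform(0.03, 0.12))

    states = [HealthState("start", "Event-free", u_start)]
    rules: list[TransitionRule] = [
        TransitionRule("shared", ANY_ALIVE, "bsc", hazard),
        TransitionRule("shared", "bsc", "death", 1.0),
    ]
    orderings: list[list[str]] = []

    # graded adverse-event families with monotone utilities by construction
    ae_ids: list[str] = []
    fam = 0
    remaining = n_ae_states
    while remaining > 0:
        grades = int(min(remaining, rng.integers(1, 4)))
        remaining -= grades
        fam += 1
        utils = np.sort(rng.uniform(0.3, u_start, size=grades))[::-1]
        chain = []
        for g in range(grades):
            sid = f"ae{fam}_g{g + 1}"
            severe = g == grades - 1 and grades > 1
            states.append(
                HealthState(
                    sid,
                    f"Family {fam} grade {g + 1}",
                    float(utils[g]),
                    extra_cycle_cost=float(rng.integers(0, 60_000)) if g > 0 else 0.0,
                    entry_cost=float(rng.integers(100_000, 600_000)) if severe else 0.0,
                )
            )
            chain.append(sid)
            ae_ids.append(sid)
            if g > 0:  # improvement toward the previous grade
                rules.append(
                    TransitionRule("shared", sid, chain[g - 1], float(rng.uniform(0.1, 0.4)))
                )
        if len(chain) > 1:
            orderings.append(chain)

    if with_tunnel and ae_ids:
        worst = ae_ids[-1]
        worst_utility = next(s.utility for s in states if s.id == worst)
        states.append(
            HealthState(
                "tunnel",
                "Intervention (one cycle)",
                worst_utility,  # tunnels keep the severity of the state they treat
                entry_cost=float(rng.integers(200_000, 700_000)),
            )
        )
        states.append(HealthState("post_tunnel", "Post-intervention", u_start))
        rules.append(TransitionRule("shared", worst, "tunnel", float(rng.uniform(0.05, 0.2))))
        rules.append(TransitionRule("shared", "tunnel", "post_tunnel", None))

    states.append(
        HealthState(
            "bsc", "Terminal care", 0.0,
            entry_cost=float(rng.integers(300_000, 900_000)),
            followup="none", is_terminal_care=True,
        )
    )
    states.append(HealthState("death", "Death", 0.0, followup="none", is_absorbing=True))

    # arm-specific onset probabilities; arm A is the gentler treatment
    if ae_ids:
        raw = rng.uniform(0.005, 0.08, size=len(ae_ids))
        budget = 0.85 - hazard
        if raw.sum() > budget:
            raw *= budget / raw.sum()
        reduction = rng.uniform(0.05, 0.8, size=len(ae_ids))
        for sid, p_b, f in zip(ae_ids, raw, reduction):
            rules.append(TransitionRule("B", "start", sid, float(p_b), 1, onset_window))
            rules.append(TransitionRule("A", "start", sid, float(p_b * f), 1, onset_window))

    model = ModelDefinition(
        states=states,
        rules=rules,
        strategies=[
            StrategyDefinition("A", float(rng.integers(1_500_000, 3_000_000))),
            StrategyDefinition("B", float(rng.integers(500_000, 1_000_000))),
        ],
        settings=ModelSettings(
            cycle_length_months=3.0,
            horizon_cycles=horizon,
            annual_discount_rate=0.03,
            wtp_threshold=7_500_000.0,
            followup_cost_year1=float(rng.integers(20_000, 60_000)),
            followup_cost_later=float(rng.integers(10_000, 40_000)),
            admission_cost=float(rng.integers(500_000, 2_000_000)),
        ),
        start_state="start",
        utility_orderings=orderings,
    )
    problems = validate(model)
    if problems:  # pragma: no cover - generator guarantees validity
        raise AssertionError("generator produced an invalid model: " + "; ".join(problems))
    return model


def perturb_model(
    model: ModelDefinition, relative_width: float = 0.2, seed: int = 0
) -> ModelDefinition:
    """One triangular-distribution draw of a model, as a standalone model.

    Bridges the probabilistic-sensitivity sampler into property tests:
    ``relative_width=0`` returns an identical copy; otherwise every
    perturbable scalar lies within ``±relative_width`` of its base.
    """
    rng = np.random.default_rng(seed)
    sampled, _ = sample_draw(model, rng, width=relative_width)
    return sampled
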