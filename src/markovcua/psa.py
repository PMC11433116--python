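"""Probabilistic sensitivity analysis and acceptability curves.

Every scalar parameter is drawn from a triangular distribution centred on
its base value with ±20% support (see :mod:`markovcua.params`); both arms
are evaluated on each draw and the paired (ΔCost, ΔQALY) results yield
the cost-effectiveness acceptability curve: the fraction of draws with
positive net monetary benefit ``wtp × ΔE − ΔC`` at each willingness to
pay.

By default each arm is evaluated on its *own* independent draw of the
parameter vector (``arm_correlation="independent"``): the two treatment
subtrees carry separate distribution nodes, so utilities and costs vary
between arms within a draw.  ``arm_correlation="shared"`` instead applies
one common draw to both arms, so only arm-specific transition
probabilities differ.  Structural scalars — the fixed radiotherapy fees
and the shared survival hazard — are never sampled in either mode.

Draw ``i`` uses an independent substream spawned from the master seed, so
increasing ``n_draws`` extends a run without changing earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import compare
from .engine import run_strategy
from .model import ModelDefinition
from .packaged import packaged_model
from .params import DrawFlags, sample_draw

__all__ = ["PsaDraw", "PsaResult", "run_psa", "run_psa_model", "ceac", "default_wtp_grid"]


def default_wtp_grid(stop: float = 20_000_000.0, step: float = 500_000.0) -> np.ndarray:
    """Willingness-to-pay grid: 0 to 20M yen in 500k steps (includes 7.5M)."""
    return np.arange(0.0, stop + step / 2, step)


@dataclass
class PsaDraw:
    draw_index: int
    delta_cost: float
    delta_qaly: float
    icer: float | None
    flags: DrawFlags
    model: ModelDefinition | None = None


@dataclass
class PsaResult:
    seed: int
    n_draws: int
    width: float
    wtp_threshold: float
    draws: list[PsaDraw] = field(default_factory=list)

    @property
    def delta_cost(self) -> np.ndarray:
        return np.array([d.delta_cost for d in self.draws])

    @property
    def delta_qaly(self) -> np.ndarray:
        return np.array([d.delta_qaly for d in self.draws])

    def prob_cost_effective(self, wtp: float | None = None) -> float:
        """Fraction of draws with positive net monetary benefit at ``wtp``."""
        if wtp is None:
            wtp = self.wtp_threshold
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0))

    def ceac(self, wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
        return ceac(self, wtp_grid)

    def to_frame(self) -> pd.DataFrame:
        """Draw-level table (CSV-ready)."""
        return pd.DataFrame(
            {
                "draw": [d.draw_index for d in self.draws],
                "delta_cost": [d.delta_cost for d in self.draws],
                "delta_qaly": [d.delta_qaly for d in self.draws],
                "icer": [d.icer for d in self.draws],
                "constraint_fallback": [d.flags.any for d in self.draws],
            }
        )

    def shift_fee(self, fee_delta: float) -> "PsaResult":
        """The same draws under a different comparator upfront fee.

        The fee is fixed (never sampled) and charged undiscounted at time
        zero, so a fee change shifts every draw's ΔCost by exactly
        ``fee_delta`` with ΔQALY unchanged.
        """
        out = PsaResult(self.seed, self.n_draws, self.width, self.wtp_threshold)
        for d in self.draws:
            dc = d.delta_cost + fee_delta
            out.draws.append(
                PsaDraw(d.draw_index, dc, d.delta_qaly,
                        dc / d.delta_qaly if d.delta_qaly != 0 else None, d.flags)
            )
        return out


def run_psa_model(
    model: ModelDefinition,
    n_draws: int = 1000,
    seed: int = 0,
    comparator: str = "PBT",
    reference: str = "3DCRT",
    width: float = 0.2,
    arm_correlation: str = "independent",
    store_models: bool = False,
) -> PsaResult:
    """Monte Carlo parameter uncertainty analysis of any two-arm model."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if arm_correlation not in ("independent", "shared"):
        raise ValueError("arm_correlation must be 'independent' or 'shared'")
    result = PsaResult(
        seed=seed,
        n_draws=n_draws,
        width=width,
        wtp_threshold=model.settings.wtp_threshold,
    )
    children = np.random.SeedSequence(seed).spawn(n_draws)
    for i in range(n_draws):
        rng = np.random.default_rng(children[i])
        sampled_c, flags = sample_draw(model, rng, width=width)
        if arm_correlation == "independent":
            sampled_r, flags_r = sample_draw(model, rng, width=width)
            flags.utility_sort_fallback.extend(flags_r.utility_sort_fallback)
            flags.row_rescale_fallback.extend(flags_r.row_rescale_fallback)
        else:
            sampled_r = sampled_c
        out_c = run_strategy(sampled_c, comparator, check=False)
        out_r = run_strategy(sampled_r, reference, check=False)
        cea = compare(out_c, out_r, model.settings.wtp_threshold)
        result.draws.append(
            PsaDraw(
                draw_index=i,
                delta_cost=cea.delta_cost,
                delta_qaly=cea.delta_qaly,
                icer=cea.icer,
                flags=flags,
                model=sampled_c if store_models else None,
            )
        )
    return result


def run_psa(
    fee_level: str = "rare",
    n_draws: int = 1000,
    seed: int = 0,
    width: float = 0.2,
    arm_correlation: str = "independent",
    store_models: bool = False,
) -> PsaResult:
    """PSA of the packaged model at one fee level."""
    return run_psa_model(
        packaged_model(fee_level), n_draws=n_draws, seed=seed, width=width,
        arm_correlation=arm_correlation, store_models=store_models,
    )


def ceac(result: PsaResult, wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve on a willingness-to-pay grid.

    At each grid point the acceptability is the fraction of draws with
    positive net monetary benefit, which coincides with the fraction of
    draws whose ICER is below the threshold whenever every draw has
    positive incremental effectiveness.
    """
    if not result.draws:
        raise ValueError("PSA result contains no draws")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    dc = result.delta_cost
    de = result.delta_qaly
    frac = [(float(np.mean(w * de - dc > 0))) for w in wtp_grid]
    return pd.DataFrame({"wtp": np.asarray(wtp_grid, dtype=float), "prob_cost_effective": frac})
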