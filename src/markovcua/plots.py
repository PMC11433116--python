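"""Publication-shaped figures: tornado diagram and acceptability curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .owsa import OwsaEntry

__all__ = ["tornado_figure", "ceac_figure"]


def tornado_figure(
    entries: list[OwsaEntry],
    base_icer: float,
    top: int = 10,
    wtp: float | None = None,
):
    """Horizontal-bar tornado diagram of the ``top`` widest ICER ranges."""
    shown = entries[:top][::-1]
    fig, ax = plt.subplots(figsize=(8, 0.5 * len(shown) + 1.5))
    for y, e in enumerate(shown):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(y, hi - lo, left=lo, height=0.6, color="#4878d0")
    ax.axvline(base_icer, color="black", lw=1, label="base-case ICER")
    if wtp is not None:
        ax.axvline(wtp, color="crimson", lw=1, ls="--", label="WTP threshold")
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.parameter_id for e in shown])
    ax.set_xlabel("ICER (yen per QALY)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    return fig


def ceac_figure(curve: pd.DataFrame, wtp: float | None = None):
    """Cost-effectiveness acceptability curve (probability vs WTP)."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(curve["wtp"], curve["prob_cost_effective"], marker="o", ms=3)
    if wtp is not None:
        ax.axvline(wtp, color="crimson", lw=1, ls="--", label="WTP threshold")
        ax.legend(loc="lower right", fontsize=8)
    ax.set_xlabel("Willingness to pay (yen per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    return fig
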