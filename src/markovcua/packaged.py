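"""The packaged locally-advanced-esophageal-cancer (LAEC) model.

Two identical models differing only in the proton-beam-therapy fee are
shipped as YAML data files: the ``"rare"`` base case uses the higher
social-insurance fee for rare cancers (2,375,000 yen) and ``"non_rare"``
the lower fee (1,600,000 yen).  All other parameters — seventeen health
states covering graded radiation pneumonitis (RP), pleural effusion (PE)
and pericardial effusion (PCE) plus their overlaps, drainage and
pericardiotomy tunnel states, best supportive care and death; per-cycle
transition probabilities windowed to the first year (RP onset) or first
two years (PE/PCE onset); utility weights; and social-insurance costs —
are shared between the two base cases.
"""

from __future__ import annotations

from importlib import resources

from .io import read_model
from .model import ModelDefinition

__all__ = ["packaged_model", "FEE_LEVELS", "FEE_DIFFERENCE"]

FEE_LEVELS = ("rare", "non_rare")

#: Yen difference between the two proton-therapy fee levels.
FEE_DIFFERENCE = 2_375_000.0 - 1_600_000.0

_FILES = {"rare": "laec_rare.yaml", "non_rare": "laec_non_rare.yaml"}


def packaged_model(fee_level: str = "rare") -> ModelDefinition:
    """Load the packaged LAEC model at the requested PBT fee level.

    Parameters
    ----------
    fee_level
        ``"rare"`` (PBT fee 2,375,000 yen) or ``"non_rare"`` (1,600,000).
    """
    if fee_level not in _FILES:
        raise ValueError(
            f"unknown fee_level {fee_level!r}; expected one of {FEE_LEVELS}"
        )
    with resources.as_file(
        resources.files("markovcua.data") / _FILES[fee_level]
    ) as path:
        return read_model(path)


def packaged_model_path(fee_level: str = "rare"):
    """Filesystem path of a packaged model data file (for CLI display)."""
    if fee_level not in _FILES:
        raise ValueError(
            f"unknown fee_level {fee_level!r}; expected one of {FEE_LEVELS}"
        )
    return resources.files("markovcua.data") / _FILES[fee_level]
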