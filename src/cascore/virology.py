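"""Viral-load categorisation and programmatic follow-up actions.

Categories follow the WHO programmatic thresholds used for routine ART
monitoring: undetectable (< 40 copies/mL, the assay detection limit),
low-level viraemia ([40, 999] copies/mL) and virological treatment
failure (>= 1000 copies/mL). Suppression is any value < 1000 copies/mL
on a single measurement. Low-level viraemia triggers re-enforced
adherence counselling; failure additionally triggers a repeat viral
load within three months.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "VLCategory",
    "FollowupAction",
    "ViralLoadResult",
    "DETECTION_LIMIT",
    "FAILURE_THRESHOLD",
    "classify_viral_load",
    "followup_action",
]

DETECTION_LIMIT = 40.0
FAILURE_THRESHOLD = 1000.0


class VLCategory(str, enum.Enum):
    UNDETECTABLE = "undetectable"
    LOW_LEVEL = "low_level"
    FAILURE = "failure"


class FollowupAction(str, enum.Enum):
    NONE = "none"
    REINFORCED_COUNSELLING = "reinforced_counselling"
    REINFORCED_PLUS_REPEAT_VL = "reinforced_plus_repeat_vl"


@dataclass(frozen=True)
class ViralLoadResult:
    """A viral load in copies/mL with its category and suppression flag.

    ``censored_below_limit`` marks values reported by the assay as below
    the detection limit ("<40" in source data); such values are stored
    as 0 copies/mL and only the category is meaningful downstream.
    """

    copies_per_ml: float
    category: VLCategory
    suppressed: bool
    censored_below_limit: bool = False


def classify_viral_load(
    copies_per_ml: float, *, censored_below_limit: bool = False
) -> ViralLoadResult:
    """Categorise a viral load measurement.

    < 40 copies/mL is undetectable, [40, 999] low-level viraemia,
    >= 1000 treatment failure; suppressed means < 1000. Boundaries:
    exactly 40 is low-level, exactly 1000 is failure, and real values in
    (999, 1000) remain low-level since failure requires >= 1000.
    """
    v = float(copies_per_ml)
    if math.isnan(v) or v < 0:
        raise ValueError(f"copies_per_ml must be a non-negative number, got {copies_per_ml}")
    if censored_below_limit and v >= DETECTION_LIMIT:
        raise ValueError(
            "a value censored below the detection limit cannot be "
            f">= {DETECTION_LIMIT} copies/mL"
        )
    if v < DETECTION_LIMIT:
        category = VLCategory.UNDETECTABLE
    elif v < FAILURE_THRESHOLD:
        category = VLCategory.LOW_LEVEL
    else:
        category = VLCategory.FAILURE
    return ViralLoadResult(
        copies_per_ml=v,
        category=category,
        suppressed=v < FAILURE_THRESHOLD,
        censored_below_limit=censored_below_limit,
    )


def followup_action(result: ViralLoadResult) -> FollowupAction:
    """Programmatic action flag for a categorised viral load."""
    if result.category is VLCategory.UNDETECTABLE:
        return FollowupAction.NONE
    if result.category is VLCategory.LOW_LEVEL:
        return FollowupAction.REINFORCED_COUNSELLING
    return FollowupAction.REINFORCED_PLUS_REPEAT_VL
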