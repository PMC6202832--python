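"""Composite adherence score (CAS) for ART adherence monitoring.

Three instruments are scored on a common ordinal scale (3 = high,
2 = moderate, 1 = low adherence):

* **pharmacy refill** — number of monthly ARV pick-ups over a 6-month
  window: 6 refills scores 3, one missed refill scores 2, two or more
  missed refills score 1;
* **self-report questionnaire** — four yes/no items phrased so that "no"
  is the adherent answer: no "yes" answers scores 3, one scores 2, two
  or more score 1;
* **visual analogue scale (VAS)** — a 0–10 self-placed mark estimating
  30-day adherence, read as a percentage (value x 10): >= 90% scores 3,
  80% to < 90% scores 2, < 80% scores 1.

The composite adherence score is the sum of the three instrument scores
(range 3–9), classified high (8–9), moderate (5–7) or low (3–4), with an
override: a low pharmacy-refill score forces the composite class to low
regardless of the sum, so that self-reported instruments cannot outvote
the objective refill record.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "AdherenceClass",
    "AdherenceMeasurement",
    "ComponentScores",
    "CASResult",
    "CASCutpoints",
    "score_refill",
    "score_selfreport",
    "score_vas",
    "score_components",
    "compute_cas",
    "score_measurement",
]

REFILL_WINDOW_MONTHS = 6
N_SELFREPORT_ITEMS = 4
VAS_MAX = 10.0


class AdherenceClass(str, enum.Enum):
    """Three-level adherence classification."""

    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AdherenceMeasurement:
    """Raw instrument readings for one woman over one assessment window.

    Parameters
    ----------
    refills_collected
        Monthly ARV refills collected in the 6-month window, 0–6.
    selfreport_yes
        Number of "yes" answers across the four questionnaire items, 0–4.
    vas_value
        Visual analogue scale reading on the 0–10 line.
    """

    refills_collected: int
    selfreport_yes: int
    vas_value: float

    def __post_init__(self) -> None:
        if not isinstance(self.refills_collected, (int,)) or isinstance(
            self.refills_collected, bool
        ):
            raise ValueError("refills_collected must be an integer")
        if not 0 <= self.refills_collected <= REFILL_WINDOW_MONTHS:
            raise ValueError(
                f"refills_collected must be in [0, {REFILL_WINDOW_MONTHS}], "
                f"got {self.refills_collected}"
            )
        if not isinstance(self.selfreport_yes, int) or isinstance(
            self.selfreport_yes, bool
        ):
            raise ValueError("selfreport_yes must be an integer")
        if not 0 <= self.selfreport_yes <= N_SELFREPORT_ITEMS:
            raise ValueError(
                f"selfreport_yes must be in [0, {N_SELFREPORT_ITEMS}], "
                f"got {self.selfreport_yes}"
            )
        if not 0.0 <= float(self.vas_value) <= VAS_MAX:
            raise ValueError(
                f"vas_value must be in [0, {VAS_MAX}], got {self.vas_value}"
            )


@dataclass(frozen=True)
class ComponentScores:
    """Per-instrument ordinal scores, each in {1, 2, 3}."""

    refill_score: int
    selfreport_score: int
    vas_score: int

    def __post_init__(self) -> None:
        for name in ("refill_score", "selfreport_score", "vas_score"):
            v = getattr(self, name)
            if v not in (1, 2, 3):
                raise ValueError(f"{name} must be 1, 2 or 3, got {v!r}")

    def astuple(self) -> tuple[int, int, int]:
        return (self.refill_score, self.selfreport_score, self.vas_score)


@dataclass(frozen=True)
class CASCutpoints:
    """Class boundaries on the composite sum.

    ``high_min`` is the smallest sum classified high, ``moderate_min``
    the smallest classified moderate; anything below is low. Defaults
    give high = {8, 9}, moderate = {5, 6, 7}, low = {3, 4}, the only
    contiguous partition consistent with the published score table.
    """

    high_min: int = 8
    moderate_min: int = 5

    def __post_init__(self) -> None:
        if not 3 < self.moderate_min < self.high_min <= 9:
            raise ValueError(
                "cut points must satisfy 3 < moderate_min < high_min <= 9"
            )

    def classify_sum(self, cas_sum: int) -> AdherenceClass:
        if cas_sum >= self.high_min:
            return AdherenceClass.HIGH
        if cas_sum >= self.moderate_min:
            return AdherenceClass.MODERATE
        return AdherenceClass.LOW


@dataclass(frozen=True)
class CASResult:
    """Composite adherence score: sum, class, and override bookkeeping."""

    cas_sum: int
    adherence_class: AdherenceClass
    refill_override_applied: bool


def score_refill(refills_collected: int) -> int:
    """Score the pharmacy-refill record.

    6 refills -> 3 (high); 5 refills (one missed) -> 2 (moderate);
    4 or fewer (two or more missed) -> 1 (low).
    """
    if isinstance(refills_collected, bool) or not isinstance(refills_collected, int):
        raise ValueError("refills_collected must be an integer")
    if not 0 <= refills_collected <= REFILL_WINDOW_MONTHS:
        raise ValueError(
            f"refills_collected must be in [0, {REFILL_WINDOW_MONTHS}], "
            f"got {refills_collected}"
        )
    missed = REFILL_WINDOW_MONTHS - refills_collected
    if missed == 0:
        return 3
    if missed == 1:
        return 2
    return 1


def score_selfreport(selfreport_yes: int) -> int:
    """Score the four-item questionnaire by its count of "yes" answers.

    0 yes -> 3; 1 yes -> 2; 2 or more -> 1.
    """
    if isinstance(selfreport_yes, bool) or not isinstance(selfreport_yes, int):
        raise ValueError("selfreport_yes must be an integer")
    if not 0 <= selfreport_yes <= N_SELFREPORT_ITEMS:
        raise ValueError(
            f"selfreport_yes must be in [0, {N_SELFREPORT_ITEMS}], "
            f"got {selfreport_yes}"
        )
    if selfreport_yes == 0:
        return 3
    if selfreport_yes == 1:
        return 2
    return 1


def score_vas(vas_value: float, *, percent_scale: bool = False) -> int:
    """Score the visual analogue scale reading.

    The instrument is a 0–10 line; percent adherence = value x 10.
    >= 90% -> 3; 80% to < 90% -> 2; < 80% -> 1 (half-open intervals, so
    exactly 90 scores 3 and exactly 80 scores 2).

    Set ``percent_scale=True`` for inputs already recorded on 0–100.
    """
    v = float(vas_value)
    upper = 100.0 if percent_scale else VAS_MAX
    if not 0.0 <= v <= upper:
        raise ValueError(f"vas_value must be in [0, {upper}], got {vas_value}")
    percent = v if percent_scale else v * 10.0
    if percent >= 90.0:
        return 3
    if percent >= 80.0:
        return 2
    return 1


def score_components(
    measurement: AdherenceMeasurement, *, vas_percent_scale: bool = False
) -> ComponentScores:
    """Score all three instruments for one measurement window."""
    return ComponentScores(
        refill_score=score_refill(measurement.refills_collected),
        selfreport_score=score_selfreport(measurement.selfreport_yes),
        vas_score=score_vas(measurement.vas_value, percent_scale=vas_percent_scale),
    )


def compute_cas(
    components: ComponentScores, cutpoints: CASCutpoints | None = None
) -> CASResult:
    """Compute the composite adherence score and class.

    The class is determined by the sum of the three component scores via
    ``cutpoints``, then forced to low whenever the refill score is 1
    (``refill_override_applied`` records when the override changed the
    class from what the sum alone implied).
    """
    cp = cutpoints if cutpoints is not None else CASCutpoints()
    cas_sum = (
        components.refill_score + components.selfreport_score + components.vas_score
    )
    cls = cp.classify_sum(cas_sum)
    override = False
    if components.refill_score == 1 and cls is not AdherenceClass.LOW:
        cls = AdherenceClass.LOW
        override = True
    return CASResult(
        cas_sum=cas_sum, adherence_class=cls, refill_override_applied=override
    )


def score_measurement(
    measurement: AdherenceMeasurement,
    cutpoints: CASCutpoints | None = None,
    *,
    vas_percent_scale: bool = False,
) -> tuple[ComponentScores, CASResult]:
    """Raw measurement -> (component scores, composite result)."""
    comp = score_components(measurement, vas_percent_scale=vas_percent_scale)
    return comp, compute_cas(comp, cutpoints)
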