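"""Per-woman cohort records and the covariate taxonomy.

One :class:`WomanRecord` holds everything the analysis needs about one
woman: baseline covariates at ART initiation, retention status at
months 6 and 12, the raw adherence measurements at each assessed
timepoint, and the month-12 viral load when performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .scoring import AdherenceMeasurement

__all__ = ["COVARIATE_LEVELS", "RISK_REFERENCE_LEVELS", "WomanRecord"]

# Canonical covariate taxonomy: every record's categorical covariates
# must use exactly these level labels.
COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("15-24", "25-34", "35+"),
    "education": ("none", "primary", "secondary+"),
    "occupation": ("unemployed", "formal", "informal"),
    "religion": ("catholic", "protestant", "pentecostal", "muslim"),
    "marital_status": ("single", "married", "other"),
    "cd4_group": ("<=350", ">350"),
    "who_stage": ("1", "2", "3", "4"),
    "art_history": ("naive", "exposed", "option_a"),
    "timing": ("before_delivery", "after_delivery"),
}

# Reference levels used in the risk-factor odds-ratio tables.
RISK_REFERENCE_LEVELS: dict[str, str] = {
    "age_group": "35+",
    "education": "secondary+",
    "occupation": "unemployed",
    "religion": "catholic",
    "cd4_group": ">350",
    "who_stage": "1",
    "marital_status": "married",
    "art_history": "naive",
    "timing": "before_delivery",
}

DISCONTINUATION_REASONS = ("ltfu", "stopped", "transferred", "died")


@dataclass(frozen=True)
class WomanRecord:
    """One woman's longitudinal record.

    Invariants enforced on construction: a measurement at a timepoint
    implies being in care at that timepoint, and being in care at month
    12 implies being in care at month 6 (re-entry is not modelled).
    """

    id: str
    covariates: dict[str, str]
    in_care_m6: bool
    in_care_m12: bool
    measurement_m6: AdherenceMeasurement | None = None
    measurement_m12: AdherenceMeasurement | None = None
    vl_m12: float | None = None
    vl_censored: bool = False
    discontinuation_reason: str | None = None

    def __post_init__(self) -> None:
        for cov, level in self.covariates.items():
            allowed = COVARIATE_LEVELS.get(cov)
            if allowed is not None and level not in allowed:
                raise ValueError(
                    f"record {self.id}: covariate {cov!r} has unknown level "
                    f"{level!r} (expected one of {allowed})"
                )
        if self.in_care_m12 and not self.in_care_m6:
            raise ValueError(
                f"record {self.id}: in care at month 12 requires in care at month 6"
            )
        if self.measurement_m6 is not None and not self.in_care_m6:
            raise ValueError(
                f"record {self.id}: month-6 measurement requires in_care_m6"
            )
        if self.measurement_m12 is not None and not self.in_care_m12:
            raise ValueError(
                f"record {self.id}: month-12 measurement requires in_care_m12"
            )
        if self.vl_m12 is not None and not self.in_care_m12:
            raise ValueError(
                f"record {self.id}: month-12 viral load requires in_care_m12"
            )
        if self.discontinuation_reason is not None:
            if self.in_care_m12:
                raise ValueError(
                    f"record {self.id}: discontinuation reason set for a woman "
                    "still in care at month 12"
                )
            if self.discontinuation_reason not in DISCONTINUATION_REASONS:
                raise ValueError(
                    f"record {self.id}: unknown discontinuation reason "
                    f"{self.discontinuation_reason!r}"
                )

    def measurement_at(self, timepoint: str) -> AdherenceMeasurement | None:
        if timepoint == "m6":
            return self.measurement_m6
        if timepoint == "m12":
            return self.measurement_m12
        raise ValueError(f"timepoint must be 'm6' or 'm12', got {timepoint!r}")
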