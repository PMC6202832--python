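"""Cohort CSV reading and writing, and config (de)serialisation.

The cohort file is a plain UTF-8 CSV (RFC-4180 quoting, mandatory
header) with one row per woman. Self-report answers are stored per
question (``q1..q4`` as yes/no); the viral-load column accepts a
number, the assay's censored token ``<40``, or an empty cell for not
measured. Unknown columns are tolerated and left untouched; missing
required columns and malformed cells are rejected with the row number
and field named.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict
from pathlib import Path

from .records import WomanRecord
from .scoring import AdherenceMeasurement, CASCutpoints
from .synthetic_cohort import CohortConfig

__all__ = [
    "COHORT_COLUMNS",
    "CohortFileError",
    "read_cohort",
    "write_cohort",
    "config_to_json",
    "config_from_json",
]


class CohortFileError(ValueError):
    """A cohort CSV failed validation; the message names row and field."""


_COVARIATE_COLUMNS = (
    "age_group",
    "education",
    "occupation",
    "religion",
    "marital_status",
    "cd4_group",
    "who_stage",
    "art_history",
    "timing",
)

_MEASUREMENT_COLUMNS = tuple(
    f"{name}_{tp}"
    for tp in ("m6", "m12")
    for name in ("refills_total", "q1", "q2", "q3", "q4", "vas")
)

COHORT_COLUMNS: tuple[str, ...] = (
    ("id",)
    + _COVARIATE_COLUMNS
    + ("in_care_m6", "in_care_m12", "discontinuation_reason")
    + _MEASUREMENT_COLUMNS
    + ("vl_copies_m12",)
)

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def _parse_bool(value: str, row: int, field: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise CohortFileError(f"row {row}: field {field!r}: not a boolean: {value!r}")


def _parse_int(value: str, row: int, field: str, lo: int, hi: int) -> int:
    try:
        n = int(value.strip())
    except ValueError:
        raise CohortFileError(
            f"row {row}: field {field!r}: not an integer: {value!r}"
        ) from None
    if not lo <= n <= hi:
        raise CohortFileError(
            f"row {row}: field {field!r}: {n} outside the valid range [{lo}, {hi}]"
        )
    return n


def _parse_measurement(
    rowdict: dict[str, str], tp: str, row: int
) -> AdherenceMeasurement | None:
    cols = [f"refills_total_{tp}", f"q1_{tp}", f"q2_{tp}", f"q3_{tp}", f"q4_{tp}", f"vas_{tp}"]
    values = [rowdict.get(c, "").strip() for c in cols]
    if all(v == "" for v in values):
        return None
    if any(v == "" for v in values):
        missing = [c for c, v in zip(cols, values) if v == ""]
        raise CohortFileError(
            f"row {row}: partial {tp} measurement; missing {missing}"
        )
    refills = _parse_int(values[0], row, cols[0], 0, 6)
    yes_count = sum(_parse_bool(v, row, c) for c, v in zip(cols[1:5], values[1:5]))
    try:
        vas = float(values[5])
    except ValueError:
        raise CohortFileError(
            f"row {row}: field {cols[5]!r}: not a number: {values[5]!r}"
        ) from None
    try:
        return AdherenceMeasurement(refills, yes_count, vas)
    except ValueError as exc:
        raise CohortFileError(f"row {row}: {exc}") from None


def _parse_vl(value: str, row: int) -> tuple[float | None, bool]:
    v = value.strip()
    if v == "":
        return None, False
    if v.lstrip("<").strip() == "40" and v.startswith("<"):
        return 0.0, True
    try:
        copies = float(v)
    except ValueError:
        raise CohortFileError(
            f"row {row}: field 'vl_copies_m12': not a number or '<40': {value!r}"
        ) from None
    if math.isnan(copies) or copies < 0:
        raise CohortFileError(
            f"row {row}: field 'vl_copies_m12': must be non-negative, got {value!r}"
        )
    return copies, False


def read_cohort(path: str | Path) -> list[WomanRecord]:
    """Read a cohort CSV into typed records.

    Raises :class:`CohortFileError` naming the row and field for any
    malformed cell; nothing is silently coerced.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortFileError(f"{path}: empty file, header row required")
        missing = [c for c in COHORT_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CohortFileError(f"{path}: missing required columns: {missing}")
        records: list[WomanRecord] = []
        for i, rowdict in enumerate(reader, start=2):  # header is line 1
            rid = (rowdict.get("id") or "").strip()
            if not rid:
                raise CohortFileError(f"row {i}: field 'id': must be non-empty")
            covs = {}
            for cov in _COVARIATE_COLUMNS:
                v = (rowdict.get(cov) or "").strip()
                if v:
                    covs[cov] = v
            in6 = _parse_bool(rowdict["in_care_m6"], i, "in_care_m6")
            in12 = _parse_bool(rowdict["in_care_m12"], i, "in_care_m12")
            reason = (rowdict.get("discontinuation_reason") or "").strip() or None
            m6 = _parse_measurement(rowdict, "m6", i)
            m12 = _parse_measurement(rowdict, "m12", i)
            vl, censored = _parse_vl(rowdict.get("vl_copies_m12", ""), i)
            try:
                records.append(
                    WomanRecord(
                        id=rid,
                        covariates=covs,
                        in_care_m6=in6,
                        in_care_m12=in12,
                        measurement_m6=m6,
                        measurement_m12=m12,
                        vl_m12=vl,
                        vl_censored=censored,
                        discontinuation_reason=reason,
                    )
                )
            except ValueError as exc:
                raise CohortFileError(f"row {i}: {exc}") from None
    return records


def _format_float(x: float) -> str:
    return repr(float(x))


def write_cohort(records: list[WomanRecord], path: str | Path) -> None:
    """Write records to the cohort CSV dialect (lossless round-trip).

    The yes-count of the questionnaire is expanded into q1..q4 with the
    first k items answered yes; a censored viral load is written as the
    assay token ``<40``.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for rec in records:
            row: list[str] = [rec.id]
            row += [rec.covariates.get(c, "") for c in _COVARIATE_COLUMNS]
            row += [
                "1" if rec.in_care_m6 else "0",
                "1" if rec.in_care_m12 else "0",
                rec.discontinuation_reason or "",
            ]
            for m in (rec.measurement_m6, rec.measurement_m12):
                if m is None:
                    row += [""] * 6
                else:
                    yes = ["yes"] * m.selfreport_yes + ["no"] * (4 - m.selfreport_yes)
                    row += [str(m.refills_collected), *yes, _format_float(m.vas_value)]
            if rec.vl_m12 is None:
                row.append("")
            elif rec.vl_censored:
                row.append("<40")
            else:
                row.append(_format_float(rec.vl_m12))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Config JSON
# ---------------------------------------------------------------------------

def config_to_json(config: CohortConfig) -> str:
    d = asdict(config)
    d["adherence_model"] = {
        f"{cov}:{lvl}": beta for (cov, lvl), beta in config.adherence_model.items()
    }
    d["cutpoints"] = {
        "high_min": config.cutpoints.high_min,
        "moderate_min": config.cutpoints.moderate_min,
    }
    return json.dumps(d, indent=2, sort_keys=True)


def config_from_json(text: str) -> CohortConfig:
    d = json.loads(text)
    if "adherence_model" in d:
        model = {}
        for key, beta in d["adherence_model"].items():
            cov, _, lvl = key.partition(":")
            if not lvl:
                raise ValueError(
                    f"adherence_model key {key!r} must be 'covariate:level'"
                )
            model[(cov, lvl)] = float(beta)
        d["adherence_model"] = model
    if "cutpoints" in d:
        d["cutpoints"] = CASCutpoints(**d["cutpoints"])
    for key in ("class_targets_m6", "class_targets_m12", "suppression_probs"):
        if key in d:
            d[key] = tuple(d[key])
    if "instrument_marginals" in d:
        d["instrument_marginals"] = {
            k: tuple(v) for k, v in d["instrument_marginals"].items()
        }
    config = CohortConfig(**d)
    config.validate()
    return config
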