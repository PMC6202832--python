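"""Cohort-level analysis pipeline.

Turns a list of :class:`~cascore.records.WomanRecord` into the four
standard outputs of an adherence/virological-response study:

1. adherence class distributions per instrument and timepoint;
2. the Spearman correlation matrix between the instruments and the
   composite score;
3. the adherence-class vs virological-failure odds-ratio tables at
   month 12, per instrument;
4. the risk-factor analysis for low adherence, with women who
   discontinued treatment by month 12 merged into the low-adherence
   outcome as the worst case (bivariate ORs, p < screening threshold
   selection plus forced covariates, and a multivariable logistic
   model reporting adjusted ORs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .epi_stats import (
    ContingencyTable,
    LogisticFit,
    ORResult,
    categorical_or,
    fit_logistic,
    odds_ratio,
    spearman_rho,
)
from .records import RISK_REFERENCE_LEVELS, WomanRecord
from .scoring import AdherenceClass, CASCutpoints, score_measurement
from .virology import classify_viral_load

__all__ = [
    "INSTRUMENTS",
    "DEFAULT_FORCED_COVARIATES",
    "DEFAULT_EXCLUSION_REASONS",
    "SuppressionTable",
    "RiskFactorTable",
    "AnalysisReport",
    "score_cohort",
    "tabulate_adherence",
    "correlation_matrix",
    "suppression_analysis",
    "risk_factor_analysis",
    "analyze_cohort",
    "round_half_up",
]

INSTRUMENTS = ("refill", "selfreport", "vas", "cas")
CLASS_ORDER = (AdherenceClass.LOW, AdherenceClass.MODERATE, AdherenceClass.HIGH)

# Covariates always carried into the multivariable model, matching the
# adjustment set of the published risk-factor table.
DEFAULT_FORCED_COVARIATES = (
    "age_group",
    "education",
    "occupation",
    "religion",
    "who_stage",
    "cd4_group",
)

# Women whose discontinuation is administrative (moved care elsewhere)
# or terminal are excluded from the worst-case merge by default.
DEFAULT_EXCLUSION_REASONS = frozenset({"transferred", "died"})


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, the convention used for printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Per-record scoring helpers
# ---------------------------------------------------------------------------

def _scores_frame(
    cohort: list[WomanRecord],
    timepoint: str,
    cutpoints: CASCutpoints | None,
) -> pd.DataFrame:
    """One row per woman with a measurement at ``timepoint``.

    Columns: id, refill/selfreport/vas component scores (1-3), cas_sum
    (3-9) and the class per instrument (component score mapped 3->high,
    2->moderate, 1->low; composite class with the refill override).
    """
    score_to_class = {3: AdherenceClass.HIGH, 2: AdherenceClass.MODERATE, 1: AdherenceClass.LOW}
    rows = []
    for rec in cohort:
        m = rec.measurement_at(timepoint)
        if m is None:
            continue
        comp, cas = score_measurement(m, cutpoints)
        rows.append(
            {
                "id": rec.id,
                "refill": comp.refill_score,
                "selfreport": comp.selfreport_score,
                "vas": comp.vas_score,
                "cas_sum": cas.cas_sum,
                "refill_class": score_to_class[comp.refill_score],
                "selfreport_class": score_to_class[comp.selfreport_score],
                "vas_class": score_to_class[comp.vas_score],
                "cas_class": cas.adherence_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "refill", "selfreport", "vas", "cas_sum",
            "refill_class", "selfreport_class", "vas_class", "cas_class",
        ],
    )


def score_cohort(
    cohort: list[WomanRecord],
    timepoint: str,
    cutpoints: CASCutpoints | None = None,
) -> pd.DataFrame:
    """Score every assessed woman at a timepoint; see :func:`_scores_frame`."""
    if timepoint not in ("m6", "m12"):
        raise ValueError(f"timepoint must be 'm6' or 'm12', got {timepoint!r}")
    return _scores_frame(cohort, timepoint, cutpoints)


# ---------------------------------------------------------------------------
# 1. Adherence distributions
# ---------------------------------------------------------------------------

def tabulate_adherence(
    cohort: list[WomanRecord],
    timepoint: str,
    cutpoints: CASCutpoints | None = None,
) -> pd.DataFrame:
    """Class counts and percentages per instrument at one timepoint.

    Returns a DataFrame indexed by (instrument, class) with columns
    ``count`` and ``percent`` over the women assessed at the timepoint.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    df = score_cohort(cohort, timepoint, cutpoints)
    n = len(df)
    rows = []
    for instrument in INSTRUMENTS:
        col = f"{instrument}_class"
        for cls in (AdherenceClass.HIGH, AdherenceClass.MODERATE, AdherenceClass.LOW):
            count = int((df[col] == cls).sum()) if n else 0
            pct = round_half_up(100.0 * count / n, 1) if n else float("nan")
            rows.append((instrument, cls.value, count, pct))
    out = pd.DataFrame(rows, columns=["instrument", "class", "count", "percent"])
    out.attrs["n_assessed"] = n
    return out.set_index(["instrument", "class"])


# ---------------------------------------------------------------------------
# 2. Instrument correlation matrix
# ---------------------------------------------------------------------------

def correlation_matrix(
    cohort: list[WomanRecord],
    timepoint: str,
    cutpoints: CASCutpoints | None = None,
) -> pd.DataFrame:
    """Pairwise Spearman correlations between instruments and the CAS.

    Uses the component scores (1-3) for the three single instruments
    and the composite sum (3-9) for the CAS. Entries that are
    undefined because a score vector is constant are NaN. The result
    is symmetric with unit diagonal; ``attrs['n']`` records the sample
    size.
    """
    df = score_cohort(cohort, timepoint, cutpoints)
    if len(df) < 3:
        raise ValueError("need at least 3 assessed records for correlations")
    vectors = {
        "refill": df["refill"].to_numpy(float),
        "selfreport": df["selfreport"].to_numpy(float),
        "vas": df["vas"].to_numpy(float),
        "cas": df["cas_sum"].to_numpy(float),
    }
    mat = pd.DataFrame(
        np.eye(len(INSTRUMENTS)), index=list(INSTRUMENTS), columns=list(INSTRUMENTS)
    )
    for i, a in enumerate(INSTRUMENTS):
        for b in INSTRUMENTS[i + 1 :]:
            try:
                rho = spearman_rho(vectors[a], vectors[b]).rho
            except ValueError:
                rho = float("nan")
            mat.loc[a, b] = rho
            mat.loc[b, a] = rho
    mat.attrs["n"] = len(df)
    return mat


# ---------------------------------------------------------------------------
# 3. Adherence vs virological suppression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuppressionTable:
    """One instrument's adherence-class vs virological-failure table.

    ``counts`` maps class -> (n_failure, n_suppressed); ``ors`` holds
    the per-class crude OR against ``reference`` (OR fixed at 1 there;
    classes with a zero cell are undefined).
    """

    instrument: str
    reference: str
    counts: dict[str, tuple[int, int]]
    ors: dict[str, ORResult]

    @property
    def n(self) -> int:
        return sum(a + b for a, b in self.counts.values())


def suppression_analysis(
    cohort: list[WomanRecord],
    cutpoints: CASCutpoints | None = None,
    alpha: float = 0.05,
    *,
    haldane: bool = False,
    cas_reference: AdherenceClass = AdherenceClass.MODERATE,
    single_reference: AdherenceClass = AdherenceClass.HIGH,
) -> dict[str, SuppressionTable]:
    """Adherence class vs virological failure at month 12, per instrument.

    Restricted to women with both a month-12 adherence measurement and
    a month-12 viral load. The outcome is treatment failure
    (>= 1000 copies/mL) vs suppression. The reference class defaults to
    high adherence for the single instruments and moderate for the
    composite score, whose high stratum can be failure-free (a zero
    cell leaves every OR against it undefined).
    """
    df = score_cohort(cohort, "m12", cutpoints)
    vl = {
        rec.id: classify_viral_load(rec.vl_m12, censored_below_limit=rec.vl_censored)
        for rec in cohort
        if rec.vl_m12 is not None
    }
    df = df[df["id"].isin(vl)].copy()
    if df.empty:
        raise ValueError("no records with both month-12 adherence and viral load")
    df["failure"] = [not vl[i].suppressed for i in df["id"]]

    out: dict[str, SuppressionTable] = {}
    for instrument in INSTRUMENTS:
        col = f"{instrument}_class"
        counts: dict[str, tuple[int, int]] = {}
        for cls in CLASS_ORDER:
            sub = df[df[col] == cls]
            counts[cls.value] = (int(sub["failure"].sum()), int((~sub["failure"]).sum()))
        ref = cas_reference if instrument == "cas" else single_reference
        # drop empty strata from the OR computation but keep their counts
        nonempty = {k: v for k, v in counts.items() if v[0] + v[1] > 0}
        if ref.value in nonempty and len(nonempty) >= 2:
            ors = categorical_or(nonempty, ref.value, alpha, haldane=haldane)
        else:
            ors = {k: ORResult.undefined(alpha) for k in nonempty}
        for cls in CLASS_ORDER:  # empty strata reported as undefined
            ors.setdefault(cls.value, ORResult.undefined(alpha))
        out[instrument] = SuppressionTable(
            instrument=instrument, reference=ref.value, counts=counts, ors=ors
        )
    return out


# ---------------------------------------------------------------------------
# 4. Risk factors for low adherence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskFactorTable:
    """Bivariate and multivariable risk-factor results.

    The outcome is low adherence at month 12 with discontinued women
    merged in as worst-case low. ``counts`` maps covariate -> level ->
    (n_low, n_not_low); ``bivariate`` the matching crude ORs;
    ``selected`` the covariates entering the multivariable model;
    ``adjusted`` maps (covariate, level) -> aOR result (empty when the
    multivariable fit failed, see ``fit_diagnosis``).
    """

    n_population: int
    n_in_care_m12: int
    n_discontinued_included: int
    n_excluded: int
    n_low: int
    counts: dict[str, dict[str, tuple[int, int]]]
    bivariate: dict[str, dict[str, ORResult]]
    selected: tuple[str, ...]
    adjusted: dict[tuple[str, str], ORResult]
    fit: LogisticFit | None
    fit_diagnosis: str = ""


def _merged_low_outcome(
    cohort: list[WomanRecord],
    cutpoints: CASCutpoints | None,
    exclusion_reasons: frozenset[str],
) -> tuple[list[WomanRecord], np.ndarray, int, int, int]:
    """Risk-analysis population and its merged low-adherence outcome.

    Women in care at month 12 contribute their composite class; women
    who discontinued are merged into the low class unless their
    discontinuation reason is in ``exclusion_reasons``.
    """
    df = score_cohort(cohort, "m12", cutpoints)
    low_by_id = dict(zip(df["id"], df["cas_class"] == AdherenceClass.LOW))
    population: list[WomanRecord] = []
    outcome: list[bool] = []
    n_in_care = n_merged = n_excluded = 0
    for rec in cohort:
        if rec.in_care_m12:
            if rec.id not in low_by_id:
                continue  # in care but not assessed: no outcome available
            n_in_care += 1
            population.append(rec)
            outcome.append(bool(low_by_id[rec.id]))
        else:
            if rec.discontinuation_reason in exclusion_reasons:
                n_excluded += 1
                continue
            n_merged += 1
            population.append(rec)
            outcome.append(True)
    return population, np.asarray(outcome, dtype=bool), n_in_care, n_merged, n_excluded


def risk_factor_analysis(
    cohort: list[WomanRecord],
    screening_alpha: float = 0.100,
    forced_covariates: tuple[str, ...] = DEFAULT_FORCED_COVARIATES,
    cutpoints: CASCutpoints | None = None,
    alpha: float = 0.05,
    *,
    exclusion_reasons: frozenset[str] = DEFAULT_EXCLUSION_REASONS,
    reference_levels: dict[str, str] | None = None,
    haldane: bool = False,
) -> RiskFactorTable:
    """Risk factors for low adherence with the worst-case merge.

    Every covariate observed in the population is cross-tabulated
    against the merged low-adherence outcome and given per-level crude
    ORs against its reference level. Covariates with any level's
    bivariate p below ``screening_alpha``, together with
    ``forced_covariates``, enter a multivariable logistic model
    (dummy-coded against the same references) whose exponentiated
    coefficients are the adjusted ORs. Empty levels are dropped from
    the dummy coding; a separated or rank-deficient multivariable fit
    is reported via ``fit_diagnosis`` with the bivariate results
    intact.
    """
    refs = dict(RISK_REFERENCE_LEVELS)
    if reference_levels:
        refs.update(reference_levels)
    population, outcome, n_in_care, n_merged, n_excluded = _merged_low_outcome(
        cohort, cutpoints, exclusion_reasons
    )
    if not population:
        raise ValueError("risk-analysis population is empty")

    covariates = sorted({c for rec in population for c in rec.covariates})
    counts: dict[str, dict[str, tuple[int, int]]] = {}
    bivariate: dict[str, dict[str, ORResult]] = {}
    for cov in covariates:
        levels: dict[str, list[int]] = {}
        for rec, low in zip(population, outcome):
            lvl = rec.covariates.get(cov)
            if lvl is None:
                continue
            pos_neg = levels.setdefault(lvl, [0, 0])
            pos_neg[0 if low else 1] += 1
        ordered = _order_levels(cov, levels, refs)
        counts[cov] = {lvl: (levels[lvl][0], levels[lvl][1]) for lvl in ordered}
        ref = refs.get(cov, ordered[-1])
        if ref in counts[cov] and len(counts[cov]) >= 2:
            bivariate[cov] = categorical_or(counts[cov], ref, alpha, haldane=haldane)
        else:
            bivariate[cov] = {lvl: ORResult.undefined(alpha) for lvl in counts[cov]}

    selected = []
    for cov in covariates:
        ps = [
            r.p_value
            for lvl, r in bivariate[cov].items()
            if r.defined and lvl != refs.get(cov)
        ]
        if cov in forced_covariates or any(p < screening_alpha for p in ps):
            selected.append(cov)

    design_cols: list[tuple[str, str]] = []
    columns = [np.ones(len(population))]
    for cov in selected:
        ref = refs.get(cov)
        for lvl in counts[cov]:
            if lvl == ref:
                continue
            col = np.array(
                [1.0 if rec.covariates.get(cov) == lvl else 0.0 for rec in population]
            )
            if col.sum() == 0:
                continue
            design_cols.append((cov, lvl))
            columns.append(col)

    adjusted: dict[tuple[str, str], ORResult] = {}
    fit = None
    diagnosis = ""
    if design_cols:
        X = np.column_stack(columns)
        fit = fit_logistic(X, outcome.astype(float))
        if fit.converged:
            cis = fit.confidence_intervals(alpha)
            ps = fit.wald_p_values()
            for j, (cov, lvl) in enumerate(design_cols, start=1):
                adjusted[(cov, lvl)] = ORResult(
                    odds_ratio=float(np.exp(fit.coefficients[j])),
                    ci_lower=float(cis[j, 0]),
                    ci_upper=float(cis[j, 1]),
                    p_value=float(ps[j]),
                    defined=True,
                    alpha=alpha,
                )
        else:
            diagnosis = fit.diagnosis or "did_not_converge"

    return RiskFactorTable(
        n_population=len(population),
        n_in_care_m12=n_in_care,
        n_discontinued_included=n_merged,
        n_excluded=n_excluded,
        n_low=int(outcome.sum()),
        counts=counts,
        bivariate=bivariate,
        selected=tuple(selected),
        adjusted=adjusted,
        fit=fit,
        fit_diagnosis=diagnosis,
    )


def _order_levels(
    cov: str, levels: dict[str, list[int]], refs: dict[str, str]
) -> list[str]:
    """Canonical taxonomy order where known, reference last otherwise."""
    from .records import COVARIATE_LEVELS

    canonical = COVARIATE_LEVELS.get(cov)
    if canonical:
        ordered = [l for l in canonical if l in levels]
        ordered += [l for l in levels if l not in ordered]
        return ordered
    ref = refs.get(cov)
    ordered = sorted(levels)
    if ref in ordered:
        ordered.remove(ref)
        ordered.append(ref)
    return ordered


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """Everything the pipeline computes, with JSON and text renderers."""

    ns: dict[str, int]
    adherence_m6: pd.DataFrame
    adherence_m12: pd.DataFrame
    correlations_m6: pd.DataFrame | None
    correlations_m12: pd.DataFrame | None
    suppression: dict[str, SuppressionTable]
    risk: RiskFactorTable

    SCHEMA_VERSION = 1

    def to_dict(self) -> dict:
        def or_dict(r: ORResult) -> dict:
            if not r.defined:
                return {"defined": False}
            return {
                "defined": True,
                "or": r.odds_ratio,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "p_value": r.p_value,
            }

        def adherence_dict(tab: pd.DataFrame) -> dict:
            out: dict[str, dict] = {}
            for (instrument, cls), row in tab.iterrows():
                out.setdefault(instrument, {})[cls] = {
                    "count": int(row["count"]),
                    "percent": float(row["percent"]),
                }
            return out

        def corr_dict(mat: pd.DataFrame | None) -> dict | None:
            if mat is None:
                return None
            return {
                "n": int(mat.attrs.get("n", 0)),
                "labels": list(mat.columns),
                "rho": [
                    [None if np.isnan(v) else float(v) for v in row]
                    for row in mat.to_numpy()
                ],
            }

        suppression = {
            inst: {
                "reference": tab.reference,
                "n": tab.n,
                "counts": {k: list(v) for k, v in tab.counts.items()},
                "odds_ratios": {k: or_dict(v) for k, v in tab.ors.items()},
            }
            for inst, tab in self.suppression.items()
        }
        risk = {
            "n_population": self.risk.n_population,
            "n_in_care_m12": self.risk.n_in_care_m12,
            "n_discontinued_included": self.risk.n_discontinued_included,
            "n_excluded": self.risk.n_excluded,
            "n_low": self.risk.n_low,
            "counts": {
                cov: {lvl: list(v) for lvl, v in levels.items()}
                for cov, levels in self.risk.counts.items()
            },
            "bivariate": {
                cov: {lvl: or_dict(r) for lvl, r in levels.items()}
                for cov, levels in self.risk.bivariate.items()
            },
            "selected": list(self.risk.selected),
            "adjusted": {
                f"{cov}:{lvl}": or_dict(r)
                for (cov, lvl), r in self.risk.adjusted.items()
            },
            "fit_diagnosis": self.risk.fit_diagnosis,
        }
        return {
            "schema_version": self.SCHEMA_VERSION,
            "ns": self.ns,
            "adherence": {
                "m6": adherence_dict(self.adherence_m6),
                "m12": adherence_dict(self.adherence_m12),
            },
            "correlations": {
                "m6": corr_dict(self.correlations_m6),
                "m12": corr_dict(self.correlations_m12),
            },
            "suppression": suppression,
            "risk_factors": risk,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        """Plain-text tables mirroring the standard report layout."""
        lines: list[str] = []

        def fmt_or(r: ORResult) -> str:
            if not r.defined:
                return "-"
            if r.odds_ratio == 1.0 and r.ci_lower == 1.0:
                return "1"
            return (
                f"{round_half_up(r.odds_ratio, 1):.1f} "
                f"({round_half_up(r.ci_lower, 1):.1f}-{round_half_up(r.ci_upper, 1):.1f})"
            )

        lines.append("== Cohort sizes ==")
        for k, v in self.ns.items():
            lines.append(f"  {k}: {v}")

        for label, tab in (("month 6", self.adherence_m6), ("month 12", self.adherence_m12)):
            lines.append("")
            lines.append(f"== Adherence distribution, {label} (n={tab.attrs.get('n_assessed', '?')}) ==")
            for (instrument, cls), row in tab.iterrows():
                lines.append(
                    f"  {instrument:<10} {cls:<9} {int(row['count']):>4} ({row['percent']:.1f})"
                )

        for label, mat in (("month 6", self.correlations_m6), ("month 12", self.correlations_m12)):
            if mat is None:
                continue
            lines.append("")
            lines.append(f"== Spearman correlations, {label} (n={mat.attrs.get('n', '?')}) ==")
            header = "  " + " " * 11 + " ".join(f"{c:>10}" for c in mat.columns)
            lines.append(header)
            for idx, row in mat.iterrows():
                cells = " ".join(
                    f"{'':>10}" if np.isnan(v) else f"{v:>10.2f}" for v in row
                )
                lines.append(f"  {idx:<11}{cells}")

        lines.append("")
        lines.append("== Adherence class vs virological failure, month 12 ==")
        for inst, tab in self.suppression.items():
            lines.append(f"  [{inst}] reference = {tab.reference} (n={tab.n})")
            for cls, (nf, ns_) in tab.counts.items():
                r = tab.ors[cls]
                lines.append(
                    f"    {cls:<9} failures {nf:>3}/{nf + ns_:<3}  OR {fmt_or(r)}"
                )

        lines.append("")
        lines.append(
            "== Risk factors for low adherence "
            f"(n={self.risk.n_population}, low={self.risk.n_low}; "
            f"{self.risk.n_discontinued_included} discontinued merged, "
            f"{self.risk.n_excluded} excluded) =="
        )
        for cov, levels in self.risk.counts.items():
            lines.append(f"  [{cov}]")
            for lvl, (nlow, nnot) in levels.items():
                biv = self.risk.bivariate[cov][lvl]
                adj = self.risk.adjusted.get((cov, lvl))
                adj_s = f"  aOR {fmt_or(adj)}" if adj is not None else ""
                lines.append(
                    f"    {lvl:<12} low {nlow:>3}/{nlow + nnot:<3}  OR {fmt_or(biv)}{adj_s}"
                )
        if self.risk.fit_diagnosis:
            lines.append(f"  multivariable fit: {self.risk.fit_diagnosis}")
        return "\n".join(lines) + "\n"


def analyze_cohort(
    cohort: list[WomanRecord],
    cutpoints: CASCutpoints | None = None,
    alpha: float = 0.05,
    screening_alpha: float = 0.100,
    *,
    haldane: bool = False,
    forced_covariates: tuple[str, ...] = DEFAULT_FORCED_COVARIATES,
    exclusion_reasons: frozenset[str] = DEFAULT_EXCLUSION_REASONS,
) -> AnalysisReport:
    """Run the full pipeline on a cohort and assemble the report.

    Correlation matrices and the suppression analysis are skipped
    (reported as None / empty) when the cohort lacks the data they
    need, so partial cohorts still produce a report.
    """
    n_m6 = sum(1 for r in cohort if r.measurement_m6 is not None)
    n_m12 = sum(1 for r in cohort if r.measurement_m12 is not None)
    n_vl = sum(
        1 for r in cohort if r.vl_m12 is not None and r.measurement_m12 is not None
    )
    adherence_m6 = tabulate_adherence(cohort, "m6", cutpoints)
    adherence_m12 = tabulate_adherence(cohort, "m12", cutpoints)
    try:
        corr_m6 = correlation_matrix(cohort, "m6", cutpoints)
    except ValueError:
        corr_m6 = None
    try:
        corr_m12 = correlation_matrix(cohort, "m12", cutpoints)
    except ValueError:
        corr_m12 = None
    try:
        suppression = suppression_analysis(cohort, cutpoints, alpha, haldane=haldane)
    except ValueError:
        suppression = {}
    risk = risk_factor_analysis(
        cohort,
        screening_alpha,
        forced_covariates,
        cutpoints,
        alpha,
        exclusion_reasons=exclusion_reasons,
        haldane=haldane,
    )
    ns = {
        "n_cohort": len(cohort),
        "n_in_care_m6": sum(1 for r in cohort if r.in_care_m6),
        "n_in_care_m12": sum(1 for r in cohort if r.in_care_m12),
        "n_assessed_m6": n_m6,
        "n_assessed_m12": n_m12,
        "n_with_vl_m12": n_vl,
        "n_risk_population": risk.n_population,
    }
    return AnalysisReport(
        ns=ns,
        adherence_m6=adherence_m6,
        adherence_m12=adherence_m12,
        correlations_m6=corr_m6,
        correlations_m12=corr_m12,
        suppression=suppression,
        risk=risk,
    )
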