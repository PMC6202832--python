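"""Synthetic Option B+ cohort generator.

No individual-level data from the study are deposited, so this module
generates cohorts with the statistical structure the analysis assumes:

* baseline covariates drawn independently from the published marginal
  distributions of the cohort;
* two-stage retention (in care at month 6, then month 12 given month
  6) matching the published retention fractions, with a categorical
  discontinuation reason for women who leave care;
* a binary logistic model linking covariates (age group, education,
  occupation by default) to the probability of low composite adherence,
  with its intercept calibrated numerically so the marginal class
  probabilities hit the configured targets exactly in expectation;
* component instrument scores drawn, conditional on the composite
  class, from a shared-latent-propensity model (one standard-normal
  propensity per woman plus independent per-instrument noise), which
  produces realistic disagreement between instruments — the VAS noise
  is smallest, making it the component that tracks the composite most
  closely;
* raw measurements (refill counts, yes-counts, VAS marks) back-filled
  from the scores so the records round-trip through the scoring rules;
* month-12 viral load drawn from the configured suppression
  probability given the composite class, with copies/mL log-uniform
  within the category bounds (the within-category distribution is an
  arbitrary choice; only the category matters downstream).

Everything is driven by one :class:`CohortConfig`; the same seed
always reproduces the same cohort.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .records import WomanRecord
from .scoring import (
    AdherenceClass,
    AdherenceMeasurement,
    CASCutpoints,
    ComponentScores,
    compute_cas,
)

__all__ = ["CohortConfig", "CalibrationError", "simulate_cohort", "worked_example_cohort"]


class CalibrationError(ValueError):
    """The configured class targets cannot be met by the adherence model."""


def _check_probs(name: str, probs: dict[str, float]) -> None:
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {total!r}, not 1")
    for lvl, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}[{lvl!r}] = {p} outside [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the published study conditions: covariate
    marginals of the baseline table, retention 217/268 at month 6 and
    185/217 at month 12 given month 6, composite class fractions
    (62.7/24.9/12.4% at month 12, 59.0/31.4/9.6% at month 6),
    suppression given class (1.0, 0.895, 0.529) and the undetectable
    fraction among suppressed (139/153). The adherence-model
    coefficients are log odds of low adherence sign-matched to the
    published bivariate risk-factor ORs.
    """

    n_women: int = 268
    seed: int = 0

    covariate_marginals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "age_group": {"15-24": 0.284, "25-34": 0.582, "35+": 0.134},
            "education": {"none": 0.019, "primary": 0.548, "secondary+": 0.433},
            "occupation": {"unemployed": 0.392, "formal": 0.052, "informal": 0.556},
            "religion": {
                "catholic": 0.220,
                "protestant": 0.388,
                "pentecostal": 0.373,
                "muslim": 0.019,
            },
            "marital_status": {"single": 0.224, "married": 0.638, "other": 0.138},
            "cd4_group": {"<=350": 0.429, ">350": 0.571},
            "who_stage": {"1": 0.843, "2": 0.131, "3": 0.026},
            "art_history": {"naive": 0.873, "exposed": 0.015, "option_a": 0.112},
            "timing": {"before_delivery": 0.944, "after_delivery": 0.056},
        }
    )

    p_in_care_m6: float = 217 / 268
    p_in_care_m12_given_m6: float = 185 / 217
    discontinuation_reasons: dict[str, float] = field(
        default_factory=lambda: {
            "ltfu": 0.50,
            "stopped": 0.25,
            "transferred": 0.15,
            "died": 0.10,
        }
    )

    # log odds-ratios of low composite adherence per covariate level
    # (levels absent here, including each reference level, carry 0)
    adherence_model: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("age_group", "15-24"): math.log(2.4),
            ("age_group", "25-34"): math.log(1.6),
            ("education", "primary"): math.log(2.6),
            ("occupation", "formal"): math.log(2.0),
            ("occupation", "informal"): math.log(2.2),
        }
    )

    # composite class targets (high, moderate, low) per timepoint
    class_targets_m6: tuple[float, float, float] = (0.590, 0.314, 0.096)
    class_targets_m12: tuple[float, float, float] = (0.627, 0.249, 0.124)

    # instrument marginals (high, moderate, low) shaping the latent
    # component model, and per-instrument latent noise s.d. — the VAS
    # noise is smallest so Spearman(VAS, composite) lands near 0.8
    instrument_marginals: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "refill": (0.811, 0.065, 0.124),
            "selfreport": (0.773, 0.168, 0.059),
            "vas": (0.730, 0.135, 0.135),
        }
    )
    instrument_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"refill": 0.9, "selfreport": 1.1, "vas": 0.45}
    )

    p_vl_measured: float = 165 / 185
    # P(VL < 1000 | composite class high, moderate, low)
    suppression_probs: tuple[float, float, float] = (1.0, 0.895, 0.529)
    p_undetectable_given_suppressed: float = 139 / 153
    vl_failure_log10_max: float = 5.5

    cutpoints: CASCutpoints = field(default_factory=CASCutpoints)

    def validate(self) -> None:
        if self.n_women < 0:
            raise ValueError("n_women must be non-negative")
        for cov, marg in self.covariate_marginals.items():
            _check_probs(f"covariate_marginals[{cov!r}]", marg)
        _check_probs("discontinuation_reasons", self.discontinuation_reasons)
        for name, t in (
            ("class_targets_m6", self.class_targets_m6),
            ("class_targets_m12", self.class_targets_m12),
        ):
            _check_probs(name, dict(zip(("high", "moderate", "low"), t)))
        for inst, t in self.instrument_marginals.items():
            _check_probs(f"instrument_marginals[{inst!r}]", dict(zip("hml", t)))
        for p_name in ("p_in_care_m6", "p_in_care_m12_given_m6", "p_vl_measured",
                       "p_undetectable_given_suppressed"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{p_name} = {p} outside [0, 1]")
        for i, p in enumerate(self.suppression_probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"suppression_probs[{i}] = {p} outside [0, 1]")
        for cov, lvl in self.adherence_model:
            marg = self.covariate_marginals.get(cov)
            if marg is None or lvl not in marg:
                raise ValueError(
                    f"adherence_model refers to unknown covariate level ({cov!r}, {lvl!r})"
                )


# ---------------------------------------------------------------------------
# Calibration: intercepts and class-conditional component distributions
# ---------------------------------------------------------------------------

def _model_covariates(config: CohortConfig) -> list[str]:
    return sorted({cov for cov, _ in config.adherence_model})


def _calibrate_intercept(config: CohortConfig, target_low: float) -> float:
    """Intercept of the low-adherence logistic model.

    Solves E_x[expit(b0 + eta(x))] = target_low exactly, enumerating
    the joint distribution of the covariates the model uses (they are
    drawn independently).
    """
    covs = _model_covariates(config)
    if not 0.0 < target_low < 1.0:
        raise CalibrationError(
            f"low-adherence class target {target_low} must be strictly inside (0, 1)"
        )
    cells: list[tuple[float, float]] = []  # (probability, eta)
    level_sets = [list(config.covariate_marginals[c].items()) for c in covs]
    for combo in itertools.product(*level_sets) if covs else [()]:
        p = 1.0
        eta = 0.0
        for cov, (lvl, plvl) in zip(covs, combo):
            p *= plvl
            eta += config.adherence_model.get((cov, lvl), 0.0)
        cells.append((p, eta))

    def expected_low(b0: float) -> float:
        return sum(p / (1.0 + math.exp(-(b0 + eta))) for p, eta in cells)

    try:
        return float(
            optimize.brentq(lambda b: expected_low(b) - target_low, -30.0, 30.0)
        )
    except ValueError as exc:  # pragma: no cover - requires pathological config
        raise CalibrationError(
            f"cannot calibrate intercept for low-class target {target_low}: {exc}"
        ) from exc


_TRIPLES = [
    (r, s, v) for r in (1, 2, 3) for s in (1, 2, 3) for v in (1, 2, 3)
]


def _triple_class(triple: tuple[int, int, int], cutpoints: CASCutpoints) -> AdherenceClass:
    return compute_cas(ComponentScores(*triple), cutpoints).adherence_class


def _class_conditional_triples(
    config: CohortConfig,
) -> dict[AdherenceClass, tuple[np.ndarray, np.ndarray]]:
    """Distribution over score triples within each composite class.

    The joint over the 27 triples comes from a shared standard-normal
    propensity A plus independent Gaussian noise per instrument,
    thresholded at cut points chosen so each instrument's marginal
    matches ``instrument_marginals``; the joint is then conditioned on
    the composite class of the triple.
    """
    grid = np.linspace(-6.0, 6.0, 601)
    w = norm.pdf(grid)
    w /= w.sum()

    probs_by_inst = {}
    for inst in ("refill", "selfreport", "vas"):
        p_high, _, p_low = config.instrument_marginals[inst]
        sd = config.instrument_noise_sd[inst]
        total_sd = math.sqrt(1.0 + sd * sd)
        c_high = total_sd * norm.ppf(1.0 - p_high)  # score 3 above this
        c_low = total_sd * norm.ppf(p_low)  # score 1 below this
        if c_low >= c_high:
            raise CalibrationError(
                f"instrument_marginals[{inst!r}] leave no room for the moderate score"
            )
        p1 = norm.cdf((c_low - grid) / sd)
        p3 = norm.sf((c_high - grid) / sd)
        probs_by_inst[inst] = {1: p1, 2: 1.0 - p1 - p3, 3: p3}

    joint = np.empty(27)
    for i, (r, s, v) in enumerate(_TRIPLES):
        joint[i] = float(
            np.sum(
                w
                * probs_by_inst["refill"][r]
                * probs_by_inst["selfreport"][s]
                * probs_by_inst["vas"][v]
            )
        )
    joint /= joint.sum()

    out: dict[AdherenceClass, tuple[np.ndarray, np.ndarray]] = {}
    for cls in AdherenceClass:
        mask = np.array(
            [_triple_class(t, config.cutpoints) is cls for t in _TRIPLES]
        )
        mass = joint[mask]
        if mass.sum() <= 0:
            raise CalibrationError(
                f"component model assigns zero mass to the {cls.value} class"
            )
        out[cls] = (np.flatnonzero(mask), mass / mass.sum())
    return out


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _draw_levels(
    rng: np.random.Generator, marginal: dict[str, float], n: int
) -> np.ndarray:
    levels = list(marginal)
    p = np.array([marginal[l] for l in levels])
    return np.array(levels, dtype=object)[rng.choice(len(levels), size=n, p=p / p.sum())]


def _draw_classes(
    rng: np.random.Generator,
    eta: np.ndarray,
    intercept: float,
    targets: tuple[float, float, float],
) -> np.ndarray:
    """Composite class per woman: LOW from the logistic model, then the
    high/moderate split (constant given not-low) matching the targets."""
    p_low = 1.0 / (1.0 + np.exp(-(intercept + eta)))
    t_high, t_mod, t_low = targets
    p_high_given_not_low = t_high / (t_high + t_mod)
    u = rng.random(len(eta))
    low = u < p_low
    high = rng.random(len(eta)) < p_high_given_not_low
    out = np.where(low, 2, np.where(high, 0, 1))  # 0 high, 1 moderate, 2 low
    return out


_CLASS_BY_INDEX = (AdherenceClass.HIGH, AdherenceClass.MODERATE, AdherenceClass.LOW)

# raw-measurement back-fill supports per score (refill count / yes count)
_REFILL_LOW_SUPPORT = np.array([0, 1, 2, 3, 4])
_REFILL_LOW_P = np.array([0.05, 0.05, 0.10, 0.30, 0.50])
_SR_LOW_SUPPORT = np.array([2, 3, 4])
_SR_LOW_P = np.array([0.60, 0.30, 0.10])


def _backfill_measurements(
    rng: np.random.Generator, triples: np.ndarray
) -> list[AdherenceMeasurement]:
    """Raw readings consistent with each score triple.

    VAS marks are drawn on a 0.1 grid strictly inside each score band
    so scoring the raw record reproduces the triple exactly.
    """
    n = len(triples)
    refill = np.where(
        triples[:, 0] == 3, 6,
        np.where(
            triples[:, 0] == 2, 5,
            rng.choice(_REFILL_LOW_SUPPORT, size=n, p=_REFILL_LOW_P),
        ),
    )
    sr = np.where(
        triples[:, 1] == 3, 0,
        np.where(
            triples[:, 1] == 2, 1,
            rng.choice(_SR_LOW_SUPPORT, size=n, p=_SR_LOW_P),
        ),
    )
    vas_tenths = np.where(
        triples[:, 2] == 3,
        rng.integers(90, 101, size=n),
        np.where(
            triples[:, 2] == 2,
            rng.integers(80, 90, size=n),
            rng.integers(30, 80, size=n),
        ),
    )
    return [
        AdherenceMeasurement(int(r), int(s), float(v) / 10.0)
        for r, s, v in zip(refill, sr, vas_tenths)
    ]


def simulate_cohort(config: CohortConfig | None = None, **overrides) -> list[WomanRecord]:
    """Generate a synthetic cohort under ``config``.

    Keyword overrides are applied on top of the (default) config, e.g.
    ``simulate_cohort(n_women=500, seed=7)``. The same config always
    produces the same cohort.
    """
    config = replace(config or CohortConfig(), **overrides) if overrides else (
        config or CohortConfig()
    )
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_women
    if n == 0:
        return []

    covariates = {
        cov: _draw_levels(rng, marg, n)
        for cov, marg in config.covariate_marginals.items()
    }

    eta = np.zeros(n)
    for (cov, lvl), beta in config.adherence_model.items():
        eta += beta * (covariates[cov] == lvl)

    b0_m6 = _calibrate_intercept(config, config.class_targets_m6[2])
    b0_m12 = _calibrate_intercept(config, config.class_targets_m12[2])
    cls_m6 = _draw_classes(rng, eta, b0_m6, config.class_targets_m6)
    cls_m12 = _draw_classes(rng, eta, b0_m12, config.class_targets_m12)

    cond = _class_conditional_triples(config)
    triple_array = np.array(_TRIPLES)

    def draw_triples(cls_idx: np.ndarray) -> np.ndarray:
        out = np.empty((len(cls_idx), 3), dtype=int)
        for ci, cls in enumerate(_CLASS_BY_INDEX):
            mask = cls_idx == ci
            if not mask.any():
                continue
            idx, p = cond[cls]
            out[mask] = triple_array[rng.choice(idx, size=int(mask.sum()), p=p)]
        return out

    triples_m6 = draw_triples(cls_m6)
    triples_m12 = draw_triples(cls_m12)
    meas_m6 = _backfill_measurements(rng, triples_m6)
    meas_m12 = _backfill_measurements(rng, triples_m12)

    in_care_m6 = rng.random(n) < config.p_in_care_m6
    in_care_m12 = in_care_m6 & (rng.random(n) < config.p_in_care_m12_given_m6)
    reasons = _draw_levels(rng, config.discontinuation_reasons, n)

    vl_measured = in_care_m12 & (rng.random(n) < config.p_vl_measured)
    p_supp = np.array(config.suppression_probs)[cls_m12]
    suppressed = rng.random(n) < p_supp
    undetectable = rng.random(n) < config.p_undetectable_given_suppressed
    log_low = rng.uniform(math.log(40.0), math.log(999.0), size=n)
    log_fail = rng.uniform(
        math.log(1000.0), config.vl_failure_log10_max * math.log(10.0), size=n
    )

    records: list[WomanRecord] = []
    width = max(4, len(str(n)))
    for i in range(n):
        covs = {cov: str(vals[i]) for cov, vals in covariates.items()}
        m6 = meas_m6[i] if in_care_m6[i] else None
        m12 = meas_m12[i] if in_care_m12[i] else None
        vl = None
        censored = False
        if vl_measured[i]:
            if suppressed[i]:
                if undetectable[i]:
                    vl, censored = 0.0, True
                else:
                    vl = round(float(np.exp(log_low[i])), 1)
            else:
                vl = round(float(np.exp(log_fail[i])), 1)
        records.append(
            WomanRecord(
                id=f"W{i + 1:0{width}d}",
                covariates=covs,
                in_care_m6=bool(in_care_m6[i]),
                in_care_m12=bool(in_care_m12[i]),
                measurement_m6=m6,
                measurement_m12=m12,
                vl_m12=vl,
                vl_censored=censored,
                discontinuation_reason=None if in_care_m12[i] else str(reasons[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Deterministic worked example
# ---------------------------------------------------------------------------

def worked_example_cohort() -> list[WomanRecord]:
    """A fixed 165-woman cohort reproducing the published composite
    class vs suppression cross-tabulation exactly.

    110 high-class women, all suppressed; 38 moderate with 4 failures;
    17 low with 8 failures — so the low-vs-moderate failure OR is
    (8x34)/(9x4) = 7.6 and the high stratum, having zero failures,
    yields an undefined OR. Intended for end-to-end regression tests
    and as the worked example of the documentation; entirely synthetic.
    """
    # (triple, n, n_failures) blocks per composite class
    blocks = [
        # high: 110 women, 0 failures
        ((3, 3, 3), 70, 0),
        ((3, 3, 2), 40, 0),
        # moderate: 38 women, 4 failures
        ((3, 2, 2), 14, 2),
        ((2, 2, 2), 12, 1),
        ((3, 3, 1), 7, 1),
        ((2, 2, 1), 5, 0),
        # low: 17 women, 8 failures
        ((1, 1, 1), 7, 5),
        ((2, 1, 1), 4, 2),
        ((1, 2, 2), 3, 1),
        ((1, 3, 3), 3, 0),
    ]
    raw = {3: (6, 0, 9.5), 2: (5, 1, 8.5), 1: (3, 2, 6.0)}
    age = ("15-24", "25-34", "35+")
    edu = ("primary", "secondary+", "none")
    occ = ("informal", "unemployed", "formal")
    rel = ("pentecostal", "protestant", "catholic", "muslim")
    mar = ("married", "single", "other")
    cd4 = (">350", "<=350")
    who = ("1", "1", "1", "2", "1", "1", "3")
    art = ("naive", "naive", "naive", "naive", "naive", "naive", "naive", "option_a")
    tim = ("before_delivery",) * 16 + ("after_delivery",)

    records: list[WomanRecord] = []
    i = 0
    fail_values = [1500.0, 3200.0, 12000.0, 25000.0, 48000.0, 80000.0,
                   150000.0, 5600.0, 2300.0, 9800.0, 31000.0, 64000.0]
    n_fail_used = 0
    for triple, count, n_fail in blocks:
        refill_score, sr_score, vas_score = triple
        r_raw = raw[refill_score][0]
        s_raw = raw[sr_score][1]
        v_raw = raw[vas_score][2]
        for k in range(count):
            failing = k < n_fail
            if failing:
                vl = fail_values[n_fail_used % len(fail_values)]
                n_fail_used += 1
                censored = False
            elif i % 10 == 0:
                vl, censored = 120.0, False  # low-level replication
            else:
                vl, censored = 0.0, True  # "<40"
            m = AdherenceMeasurement(r_raw, s_raw, v_raw)
            records.append(
                WomanRecord(
                    id=f"EX{i + 1:03d}",
                    covariates={
                        "age_group": age[i % 3],
                        "education": edu[i % 3] if i % 31 else "none",
                        "occupation": occ[i % 3],
                        "religion": rel[i % 4],
                        "marital_status": mar[i % 3],
                        "cd4_group": cd4[i % 2],
                        "who_stage": who[i % 7],
                        "art_history": art[i % 8],
                        "timing": tim[i % 17],
                    },
                    in_care_m6=True,
                    in_care_m12=True,
                    measurement_m6=m,
                    measurement_m12=m,
                    vl_m12=vl,
                    vl_censored=censored,
                )
            )
            i += 1
    assert len(records) == 165
    return records
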