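# Methods

## Scoring model

Each of the three adherence instruments maps to an ordinal score in
{1, 2, 3}: pharmacy refill by missed pick-ups in the 6-month window
(0 missed → 3, 1 → 2, ≥ 2 → 1), the four-item questionnaire by its
count of "yes" answers (0 → 3, 1 → 2, ≥ 2 → 1), and the VAS by
percent adherence = 10 × the 0–10 mark with half-open bands
[90, 100] → 3, [80, 90) → 2, [0, 80) → 1 (boundaries 90 and 80 belong
to the higher band). The composite score is the sum (3–9), classified
high {8, 9}, moderate {5, 6, 7}, low {3, 4}. These cut points are the
only contiguous partition consistent with the published score table,
whose column-to-label alignment is typographically ambiguous; they are
exposed in `CASCutpoints` so an alternative reading can be tested. The
refill override (refill score 1 ⇒ composite low) is applied after the
sum-based classification and flagged when it changed the class. Sums
of 7 arising as (3, 3, 1) and (3, 2, 2) are treated identically.

Partial assessment windows (fewer than 6 scheduled refills) are
rejected rather than prorated: the instrument is defined only for a
full window. Inputs recorded on a 0–100 VAS dialect are accepted
behind a flag and validated against that range.

## Viral-load categories

Undetectable < 40 copies/mL (assay detection limit), low-level
viraemia the closed interval [40, 999], failure ≥ 1000; values are
real, so 999.5 is low-level. Suppression is < 1000 on a single
measurement. Source values reported as the censored token `<40` are
stored as 0 copies/mL with a censoring flag; only the category is
used downstream. Action flags: low-level → re-enforced counselling,
failure → re-enforced counselling plus repeat VL within 3 months.

## Estimators

**Odds ratios.** For a 2×2 table the crude OR is the cross-product
ratio ad/bc (identical to the exponentiated slope of a
single-predictor logistic regression — tested as an oracle
equivalence). Confidence intervals use the Woolf method with
z = Φ⁻¹(1 − α/2) (1.959964 at 95%); p-values are two-sided Wald tests
on ln OR. A zero cell makes the estimate undefined (rendered “–” in
text output), preserving fidelity to the reference tables; a
Haldane–Anscombe +0.5 correction is available behind a flag, default
off. With the reference CAS counts the Woolf upper bound computes to
30.9 where the source table prints 30.8 — a 0.1 rounding discrepancy
we document rather than chase. Published p-values are not reproducible
in general (the printing conventions of the original software are
unknown), so p-values are never used as regression targets. No
multiple-testing correction is applied, matching the original
analysis.

**Spearman correlation.** Pearson correlation of mid-ranks, ties
assigned the mean of their sorted positions; exact under heavy ties
(the instrument scores take only 3 values). Constant vectors have no
defined rank correlation and raise.

**Logistic regression.** Bernoulli ML by iteratively reweighted least
squares (Fisher scoring): start at β = 0, solve the weighted normal
equations, halve the step while the log-likelihood decreases,
converge when max|score| < 1e-8 (max 25 iterations). Standard errors
come from the inverse observed information at the optimum. Rank
deficiency, constant outcomes and (quasi-)complete separation —
detected by runaway coefficients or perfect prediction — return a
diagnosed failure rather than numbers. Initialisation and
step-halving are standard safe choices; the original analysis used a
commercial statistics package whose internals are unspecified.

## Pipeline conventions

The suppression analysis crosses each instrument's 3-level class
against failure/suppression among women with both a month-12
measurement and a viral load. The reference level is high adherence
for the three single instruments and **moderate** for the composite —
forced by the composite high stratum being failure-free (zero cell) —
both read off the reference tables and overridable.

The risk-factor analysis takes low composite adherence at month 12 as
the outcome and merges women who discontinued treatment by month 12
into the low class as the worst case. Discontinuations recorded as
transferred-out or died are excluded from the merge by default (a
configurable exclusion set): the source analysis covers 247 of 268
women without stating which 21 were excluded, and administrative or
terminal exits are the natural candidates. Covariates with any
bivariate Wald p < 0.100, plus a forced set (age group, education,
occupation, religion, WHO stage, CD4 group), enter the multivariable
model dummy-coded against fixed reference levels (35+,
secondary-plus, unemployed, catholic, stage 1, CD4 > 350). Empty
levels are dropped from the coding; a failed multivariable fit is
reported with its diagnosis while the bivariate table stands.
Percentages and ORs are printed to 1 decimal with half-up rounding;
JSON output keeps full precision and carries a schema version.

## Synthetic cohort generator

The study's individual-level records are not deposited, so the
generator builds cohorts with the statistical structure the analysis
assumes. Only the marginals and a few conditionals are published; the
joint generative model is this package's own construction, with every
parameter exposed in `CohortConfig`:

- **Covariates** are drawn independently from the published baseline
  marginals (age 28.4/58.2/13.4%, education 1.9/54.8/43.3%,
  occupation 39.2/5.2/55.6%, and so on). Real covariates are of
  course not independent; nothing downstream relies on their joint
  structure.
- **Retention** is two-stage Bernoulli: in care at month 6 with
  probability 217/268, then at month 12 given month 6 with 185/217.
  Women out of care get a discontinuation reason (ltfu 0.50, stopped
  0.25, transferred 0.15, died 0.10), making transferred+died ≈ 25%
  of discontinuations so the default exclusion set reproduces a
  247-of-268-scale risk population. Retention is independent of
  covariates — a simplification; the real process is not.
- **Composite class** per timepoint: low adherence follows a binary
  logistic model on age group, education and occupation with log-OR
  coefficients ln 2.4 (15–24), ln 1.6 (25–34), ln 2.6 (primary),
  ln 2.0 (formal), ln 2.2 (informal), sign- and size-matched to the
  published bivariate risk table. The tiny "none" education level
  (1.9%, published OR 0.8, n.s.) carries no coefficient so every
  modelled cell stays large enough for stable ML estimation. The
  intercept is calibrated by root-finding so the expected marginal
  low fraction equals the target exactly (12.4% at month 12, 9.6% at
  month 6), enumerating the exact joint of the modelled covariates;
  infeasible targets raise a calibration error. Given not-low, the
  high/moderate split is the constant matching the class targets
  (62.7/24.9 at month 12, 59.0/31.4 at month 6). Month-6 and
  month-12 classes are conditionally independent given covariates.
- **Component scores** given the class come from a shared latent
  propensity: A ~ N(0, 1) per woman, instrument score from A plus
  independent Gaussian noise (σ = 0.9 refill, 1.1 self-report, 0.45
  VAS) thresholded so each instrument's marginal matches the
  published month-12 distribution; the implied joint over the 27
  score triples is computed by numerical integration and conditioned
  on the composite class of each triple. The small VAS noise makes
  the VAS the dominant composite component: default-config
  Spearman(VAS, CAS) ≈ 0.83, matching the published value, with the
  noise variances calibrated by forward simulation at design time.
  Raw measurements are back-filled from the scores (score 3 → 6
  refills / 0 yes / VAS on the 0.1 grid in [9, 10]; score 2 → 5 / 1 /
  [8, 9); score 1 → a skewed draw over the low band) so records
  round-trip exactly through the scoring rules and the CSV dialect.
- **Viral load** is measured for in-care women with probability
  165/185; suppression given class is Bernoulli with probabilities
  (1.0, 0.895, 0.529); suppressed values are undetectable with
  probability 139/153 (stored as censored `<40`), otherwise
  log-uniform in [40, 999]; failures are log-uniform in [1000,
  10^5.5]. The within-category distributions are arbitrary and only
  the category matters downstream.

A single NumPy `default_rng(seed)` drives every draw, so a seed fully
determines the cohort. Because viral load depends on adherence only
through the composite class, per-single-instrument failure ORs in
simulated cohorts do not reproduce the published per-instrument rows —
those are recomputed from the published counts directly where needed.
Separately, the published per-instrument failure strata are mutually
inconsistent with any single joint assignment under the scoring rules
(the composite-low failure count exceeds what the refill override
permits), so the fixed worked-example cohort reproduces the composite
cross-tabulation exactly and leaves the single-instrument strata
approximate.

## Problem sizes and what the tests show

Distributional checks run at n = 5 000–20 000 women (class targets
±3 points, suppression-given-class ±2 points, covariate χ² at
α = 0.001); estimator bias is assessed over 200 replicates of n = 2 000
with fixed seeds, requiring mean log-odds bias below 0.05 per
coefficient — at these sizes the residual small-sample ML bias
(~+0.03 on the age coefficients, whose reference cell is smallest)
sits safely inside the band. Passing these tests shows the pipeline
is correct under the generator's assumptions — independent
covariates, covariate-independent retention, class-conditional
instruments — not that those assumptions hold in any real cohort.

## Known limitations

- The generator models no month-by-month visit structure, no infant
  outcomes, and no covariate-dependent retention or VL sampling.
- Free-text reasons for missed doses and reminder aids are out of
  scope.
- Adjusted ORs from simulated cohorts need not match the published
  adjusted ORs: the merge of (covariate-independent) discontinuations
  dilutes covariate effects by design.
- Exact (Fisher/conditional) inference and random-effects models are
  deliberately not provided; the Woolf/Wald machinery mirrors the
  original analysis.
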