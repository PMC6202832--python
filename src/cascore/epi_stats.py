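"""Self-contained epidemiological statistics.

Implements the estimators the cohort analysis needs:

* 2x2 odds ratio with the Woolf (log-OR Wald) confidence interval and a
  Wald p-value — identical to the crude OR from a single-predictor
  binary logistic regression;
* expansion of a categorical exposure into per-level ORs against a
  reference level;
* tie-corrected Spearman rank correlation (Pearson correlation of
  mid-ranks);
* multivariable binary logistic regression fitted by iteratively
  reweighted least squares (IRLS), with standard errors from the
  inverse observed information.

All estimators are deterministic pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ContingencyTable",
    "ORResult",
    "SpearmanResult",
    "LogisticFit",
    "odds_ratio",
    "categorical_or",
    "spearman_rho",
    "fit_logistic",
]


# ---------------------------------------------------------------------------
# 2x2 odds ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a/b = exposed with/without outcome, c/d = reference."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("both table rows must have at least one observation")

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with Woolf CI and Wald p-value.

    ``defined`` is False when any cell is zero, in which case the
    numeric fields are NaN (the published-table convention is to print
    a dash for such strata).
    """

    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    defined: bool
    alpha: float = 0.05

    @staticmethod
    def undefined(alpha: float = 0.05) -> "ORResult":
        nan = float("nan")
        return ORResult(nan, nan, nan, nan, defined=False, alpha=alpha)

    @staticmethod
    def reference(alpha: float = 0.05) -> "ORResult":
        """The fixed OR = 1 entry reported for a reference level."""
        return ORResult(1.0, 1.0, 1.0, 1.0, defined=True, alpha=alpha)


def odds_ratio(
    table: ContingencyTable, alpha: float = 0.05, *, haldane: bool = False
) -> ORResult:
    """Crude odds ratio of a 2x2 table with Woolf confidence interval.

    OR = ad / bc; the 100(1-alpha)% CI is
    exp(ln OR +/- z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d)) and the
    p-value is the two-sided Wald test on ln OR. With any zero cell the
    estimate is undefined unless ``haldane`` applies the
    Haldane–Anscombe +0.5 continuity correction to every cell.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    a, b, c, d = (float(x) for x in table.cells())
    if min(a, b, c, d) == 0.0:
        if not haldane:
            return ORResult.undefined(alpha)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d) - np.log(b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = _sps.norm.ppf(1 - alpha / 2)
    p = 2 * _sps.norm.sf(abs(log_or) / se)
    return ORResult(
        odds_ratio=float(np.exp(log_or)),
        ci_lower=float(np.exp(log_or - z * se)),
        ci_upper=float(np.exp(log_or + z * se)),
        p_value=float(p),
        defined=True,
        alpha=alpha,
    )


def categorical_or(
    counts_by_level: dict[str, tuple[int, int]],
    reference_level: str,
    alpha: float = 0.05,
    *,
    haldane: bool = False,
) -> dict[str, ORResult]:
    """Per-level odds ratios of a categorical exposure vs a reference.

    ``counts_by_level`` maps each exposure level to its
    (outcome-positive, outcome-negative) counts. Every non-reference
    level is compared with the reference via :func:`odds_ratio`; the
    reference level itself is reported with OR fixed at 1. Iteration
    order of the input mapping is preserved.
    """
    if reference_level not in counts_by_level:
        raise ValueError(f"reference level {reference_level!r} not among levels")
    if len(counts_by_level) < 2:
        raise ValueError("need at least two exposure levels")
    ref_pos, ref_neg = counts_by_level[reference_level]
    out: dict[str, ORResult] = {}
    for level, (pos, neg) in counts_by_level.items():
        if level == reference_level:
            out[level] = ORResult.reference(alpha)
        else:
            table = ContingencyTable(a=pos, b=neg, c=ref_pos, d=ref_neg)
            out[level] = odds_ratio(table, alpha, haldane=haldane)
    return out


# ---------------------------------------------------------------------------
# Rank correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    n: int


def _midranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with tied values assigned the mean of their positions."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> SpearmanResult:
    """Tie-corrected Spearman rank correlation.

    Computed as the Pearson correlation of mid-ranks, which handles
    ties exactly. Constant input vectors have no defined rank
    correlation and raise ``ValueError``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1 or len(xa) != len(ya):
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(xa)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("correlation undefined for a constant vector")
    rx = _midranks(xa)
    ry = _midranks(ya)
    rx -= rx.mean()
    ry -= ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    return SpearmanResult(rho=rho, n=n)


# ---------------------------------------------------------------------------
# Logistic regression by IRLS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit.

    Coefficients are on the log-odds scale, intercept first when the
    design carries an intercept column. ``adjusted_odds_ratios`` are
    the exponentiated coefficients. When the fit fails (rank
    deficiency, separation, non-convergence) ``converged`` is False and
    ``diagnosis`` names the problem.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    converged: bool
    n_iterations: int
    diagnosis: str = ""
    log_likelihood: float = float("nan")

    @property
    def adjusted_odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def wald_p_values(self) -> np.ndarray:
        z = self.coefficients / self.standard_errors
        return 2 * _sps.norm.sf(np.abs(z))

    def confidence_intervals(self, alpha: float = 0.05) -> np.ndarray:
        """(k, 2) array of Wald CIs on the odds-ratio scale."""
        z = _sps.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.coefficients - z * self.standard_errors)
        hi = np.exp(self.coefficients + z * self.standard_errors)
        return np.column_stack([lo, hi])


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: sum y*eta - log(1+e^eta)
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    design: np.ndarray,
    outcome: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 25,
) -> LogisticFit:
    """Fit a binary logistic regression by IRLS.

    ``design`` is the n x k predictor matrix (include the intercept
    column explicitly); ``outcome`` is a 0/1 vector of length n.
    Iterates Fisher scoring from the zero vector with step-halving when
    a step decreases the likelihood; convergence is declared when the
    maximum absolute score (gradient) falls below ``tol``. Standard
    errors come from the inverse observed information at the optimum.

    Degenerate problems — a rank-deficient design, a constant outcome,
    or (quasi-)complete separation, which drives coefficients to
    infinity — return a fit with ``converged=False`` and a named
    diagnosis rather than raising.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != len(y):
        raise ValueError("design must be 2-D with one row per outcome element")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcome must be binary 0/1")
    n, k = X.shape
    nan = np.full(k, np.nan)

    if np.linalg.matrix_rank(X) < k:
        return LogisticFit(nan, nan, False, 0, diagnosis="rank_deficient_design")
    if y.min() == y.max():
        return LogisticFit(nan, nan, False, 0, diagnosis="complete_separation")

    beta = np.zeros(k)
    eta = X @ beta
    ll = _log_likelihood(eta, y)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            break
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return LogisticFit(
                nan, nan, False, n_iter, diagnosis="singular_information"
            )
        # step-halving keeps the likelihood non-decreasing
        t = 1.0
        for _ in range(30):
            beta_new = beta + t * step
            eta_new = X @ beta_new
            ll_new = _log_likelihood(eta_new, y)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta, eta, ll = beta_new, eta_new, ll_new
        if np.max(np.abs(beta)) > 1e2:
            # fitted log-odds running away: data are separated
            return LogisticFit(
                beta, nan, False, n_iter, diagnosis="complete_separation",
                log_likelihood=ll,
            )
    mu = 1.0 / (1.0 + np.exp(-eta))
    if np.allclose(mu, y, atol=1e-6):
        # perfect prediction: the MLE does not exist
        return LogisticFit(
            beta, np.full(k, np.nan), False, n_iter,
            diagnosis="complete_separation", log_likelihood=ll,
        )
    score = X.T @ (y - mu)
    converged = bool(np.max(np.abs(score)) < tol)
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        return LogisticFit(beta, nan, False, n_iter, diagnosis="singular_information")
    diagnosis = "" if converged else "max_iterations_reached"
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        converged=converged,
        n_iterations=n_iter,
        diagnosis=diagnosis,
        log_likelihood=ll,
    )
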