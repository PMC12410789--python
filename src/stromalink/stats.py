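"""Foundational statistics shared by every analysis stage.

Corrected odds ratios for 2x2 spot-colocalization tables, two-sided Fisher
exact tests, Benjamini-Hochberg FDR adjustment, percentile bootstrap
intervals, and the analytic power of the fixed-effects multiple-regression
F test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "OddsRatioResult",
    "PowerQuery",
    "odds_ratio",
    "fisher_exact",
    "bh_fdr",
    "percentile_bootstrap_ci",
    "ftest_power",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of spots cross-classified by presence of two cell types.

    ``a``: both present, ``b``: first only, ``c``: second only,
    ``d``: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if isinstance(v, (bool, np.bool_)):
                raise TypeError(f"cell {name} must be an integer count, got bool")
            if isinstance(v, float) or isinstance(v, np.floating):
                if float(v) != int(v):
                    raise ValueError(f"cell {name} must be an integer count, got {v}")
                object.__setattr__(self, name, int(v))
            elif not isinstance(v, (int, np.integer)):
                raise TypeError(f"cell {name} must be an integer count, got {type(v)}")
            else:
                object.__setattr__(self, name, int(v))
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be non-negative, got {v}")
        if self.total == 0:
            raise ValueError("contingency table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class OddsRatioResult:
    """Odds ratio with Woolf logit confidence interval.

    ``corrected`` is True iff the Haldane-Anscombe correction (0.5 added to
    every cell) was applied because some cell count was zero.  ``p_value``
    is the two-sided Fisher exact p on the original, uncorrected table.
    """

    or_value: float
    log_or: float
    ci_low: float
    ci_high: float
    corrected: bool
    p_value: float


@dataclass(frozen=True)
class PowerQuery:
    """Inputs of an a-priori/post-hoc power computation for a fixed-effects
    multiple regression F test (Cohen's f2 parameterization)."""

    f2: float
    alpha: float
    n_total: int
    n_predictors: int

    def __post_init__(self) -> None:
        if self.f2 < 0:
            raise ValueError("effect size f2 must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_total <= self.n_predictors + 1:
            raise ValueError(
                "n_total must exceed n_predictors + 1 (denominator df must be positive)"
            )


def odds_ratio(table: ContingencyTable2x2, ci_level: float = 0.95) -> OddsRatioResult:
    """Odds ratio OR = (a*d)/(b*c) with a Woolf (logit) confidence interval.

    When any cell is zero, the Haldane-Anscombe correction adds 0.5 to all
    four cells before the OR and its interval are computed, so the estimate
    is always finite and positive.  The attached p-value is the two-sided
    Fisher exact test on the original counts.
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")
    corrected = table.has_zero_cell
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = float(np.log(a) + np.log(d) - np.log(b) - np.log(c))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = float(sps.norm.isf((1 - ci_level) / 2))
    p = fisher_exact(table)
    return OddsRatioResult(
        or_value=float(np.exp(log_or)),
        log_or=log_or,
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        corrected=corrected,
        p_value=p,
    )


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value.

    Conditions on both margins and sums the hypergeometric probabilities of
    every table at most as probable as the observed one (scipy's two-sided
    rule).
    """
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def percentile_bootstrap_ci(samples, ci_level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval of a vector of bootstrap statistics.

    Uses linear interpolation between order statistics, e.g. the 2.5th and
    97.5th percentiles at ``ci_level=0.95``.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")
    tail = 100 * (1 - ci_level) / 2
    lo, hi = np.percentile(x, [tail, 100 - tail])
    return float(lo), float(hi)


def ftest_power(q: PowerQuery) -> float:
    """Power of the fixed-effects multiple-regression F test.

    Numerator df = number of predictors k, denominator df = N - k - 1,
    noncentrality lambda = f2 * N; power is the upper tail of the
    noncentral F beyond the central-F critical value at ``alpha``.
    """
    df1 = q.n_predictors
    df2 = q.n_total - q.n_predictors - 1
    if df2 <= 0:
        raise ValueError("denominator degrees of freedom must be positive")
    fcrit = sps.f.isf(q.alpha, df1, df2)
    lam = q.f2 * q.n_total
    if lam == 0:
        return float(q.alpha)
    return float(sps.ncf.sf(fcrit, df1, df2, lam))
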