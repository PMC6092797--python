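"""Exact tests and multiple-testing machinery shared by every analytic stage.

All tail probabilities that can become extreme (the study works with bounds
like 2.2e-16 and far smaller) are carried in log space and only
exponentiated on output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2, hypergeom, poisson
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_two_sided",
    "hypergeom_upper_tail",
    "bh_fdr",
    "poisson_upper_tail",
    "chi_squared_gof",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a 2x2 table, rows (a, b) and (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError(f"counts must be non-negative integers, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _as_counts(table) -> tuple[int, int, int, int]:
    if isinstance(table, ContingencyTable2x2):
        return table.a, table.b, table.c, table.d
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    a, b, c, d = (int(x) for x in arr.ravel())
    t = ContingencyTable2x2(a, b, c, d)  # validates
    return t.a, t.b, t.c, t.d


# Relative slack when comparing hypergeometric point masses: tables whose
# probability is equal to the observed one up to float rounding are included
# in the two-sided sum, matching the conventional "at most as probable" rule.
_TIE_EPS = 1e-13


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    p is the sum of hypergeometric probabilities of all tables with the same
    margins that are at most as probable as the observed table. A table with
    a zero margin (including the all-zero table) is degenerate and returns 1.
    """
    a, b, c, d = _as_counts(table)
    n1, n2, m1 = a + b, c + d, a + c
    n = n1 + n2
    if n == 0 or n1 == 0 or n2 == 0 or m1 == 0 or m1 == n:
        return 1.0
    lo = max(0, m1 - n2)
    hi = min(m1, n1)
    support = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(n1 + 1)
        - gammaln(support + 1)
        - gammaln(n1 - support + 1)
        + gammaln(n2 + 1)
        - gammaln(m1 - support + 1)
        - gammaln(n2 - m1 + support + 1)
        - (gammaln(n + 1) - gammaln(m1 + 1) - gammaln(n - m1 + 1))
    )
    log_obs = logpmf[a - lo]
    keep = logpmf <= log_obs + np.log1p(_TIE_EPS)
    if keep.all():  # observed table is modal: the sum is 1 by construction
        return 1.0
    # log-sum-exp over the kept tables
    m = logpmf[keep].max()
    p = float(np.exp(m) * np.exp(logpmf[keep] - m).sum())
    return min(1.0, p)


def fisher_exact_two_sided_log(table) -> float:
    """Natural log of :func:`fisher_exact_two_sided` (stable for tiny p)."""
    a, b, c, d = _as_counts(table)
    n1, n2, m1 = a + b, c + d, a + c
    n = n1 + n2
    if n == 0 or n1 == 0 or n2 == 0 or m1 == 0 or m1 == n:
        return 0.0
    lo = max(0, m1 - n2)
    hi = min(m1, n1)
    support = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(n1 + 1)
        - gammaln(support + 1)
        - gammaln(n1 - support + 1)
        + gammaln(n2 + 1)
        - gammaln(m1 - support + 1)
        - gammaln(n2 - m1 + support + 1)
        - (gammaln(n + 1) - gammaln(m1 + 1) - gammaln(n - m1 + 1))
    )
    keep = logpmf <= logpmf[a - lo] + np.log1p(_TIE_EPS)
    if keep.all():
        return 0.0
    kept = logpmf[keep]
    m = kept.max()
    return min(0.0, float(m + np.log(np.exp(kept - m).sum())))


def hypergeom_upper_tail(
    population: int, successes: int, draws: int, observed: int, log: bool = False
) -> float:
    """P(X >= observed) for X ~ Hypergeometric(population, successes, draws).

    With ``log=True`` the natural log of the tail is returned, which stays
    finite far below the smallest positive float.
    """
    for name, v in (
        ("population", population),
        ("successes", successes),
        ("draws", draws),
        ("observed", observed),
    ):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if successes > population or draws > population:
        raise ValueError("successes and draws cannot exceed the population")
    if observed > min(successes, draws):
        raise ValueError("observed exceeds min(successes, draws)")
    if log:
        return float(hypergeom.logsf(observed - 1, population, successes, draws))
    return float(hypergeom.sf(observed - 1, population, successes, draws))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def poisson_upper_tail(rate: float, k: int) -> float:
    """P(X >= k) for X ~ Poisson(rate)."""
    if not rate > 0:
        raise ValueError(f"rate must be positive, got {rate!r}")
    if int(k) != k or k < 0:
        raise ValueError(f"k must be a non-negative integer, got {k!r}")
    if k == 0:
        return 1.0
    return float(poisson.sf(k - 1, rate))


def poisson_upper_tail_log(rate: float, k: int) -> float:
    """Natural log of :func:`poisson_upper_tail`, stable far below 1e-300."""
    if not rate > 0:
        raise ValueError(f"rate must be positive, got {rate!r}")
    if int(k) != k or k < 0:
        raise ValueError(f"k must be a non-negative integer, got {k!r}")
    if k == 0:
        return 0.0
    return float(poisson.logsf(k - 1, rate))


def chi_squared_gof(observed, expected_proportion: float, continuity: bool = False) -> float:
    """1-df goodness-of-fit p for a pair of counts against a proportion.

    ``observed`` is the (in-category, out-of-category) count pair and
    ``expected_proportion`` the null probability of the first cell. No
    continuity correction by default; set ``continuity=True`` for Yates.
    """
    a, b = (int(x) for x in observed)
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    n = a + b
    if n == 0:
        raise ValueError("total count must be positive")
    if not 0.0 < expected_proportion < 1.0:
        raise ValueError("expected_proportion must lie strictly in (0, 1)")
    exp_a = n * expected_proportion
    exp_b = n - exp_a
    if exp_a == 0 or exp_b == 0:
        raise ValueError("zero expected cell")
    da, db = abs(a - exp_a), abs(b - exp_b)
    if continuity:
        da, db = max(0.0, da - 0.5), max(0.0, db - 0.5)
    stat = da**2 / exp_a + db**2 / exp_b
    return float(chi2.sf(stat, df=1))
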