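"""Independent brute-force oracles used by the statistical test suites.

Everything here works in exact integer arithmetic (``math.comb``), fully
independent of the scipy-based implementations it checks.
"""

from math import comb, exp, factorial


def fisher_two_sided_enumeration(a, b, c, d) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins.

    Sums the exact integer hypergeometric weights of all tables at most as
    probable as the observed one; ties are exact integer comparisons.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(c1, r1)
    weights = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    total = comb(n, c1)
    kept = sum(w for w in weights if w <= w_obs)
    return kept / total


def family_two_sided(n, r1, c1):
    """All two-sided Fisher p values for margin family (total n, row1 r1,
    col1 c1), returned as {a: p}. Exact integers throughout; the "at most
    as probable" sum uses sorted prefix sums with exact tie handling."""
    from bisect import bisect_right

    r2 = n - r1
    lo, hi = max(0, c1 - r2), min(c1, r1)
    weights = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    total = comb(n, c1)
    srt = sorted(weights)
    prefix = [0]
    for w in srt:
        prefix.append(prefix[-1] + w)
    out = {}
    for i, w_obs in enumerate(weights):
        k = bisect_right(srt, w_obs)
        out[lo + i] = prefix[k] / total
    return out


def hypergeom_tail_enumeration(population, successes, draws, observed) -> float:
    """P(X >= observed) by direct summation of binomial-coefficient terms."""
    total = comb(population, draws)
    hi = min(successes, draws)
    s = sum(
        comb(successes, k) * comb(population - successes, draws - k)
        for k in range(observed, hi + 1)
    )
    return s / total


def family_upper_tail(population, successes, draws):
    """Upper-tail p for every feasible observed count of one family."""
    total = comb(population, draws)
    lo = max(0, draws - (population - successes))
    hi = min(successes, draws)
    weights = [
        comb(successes, k) * comb(population - successes, draws - k)
        for k in range(lo, hi + 1)
    ]
    out = {}
    acc = 0
    for i in range(len(weights) - 1, -1, -1):
        acc += weights[i]
        out[lo + i] = acc / total
    return out


def poisson_tail_series(rate, k, terms=400) -> float:
    """P(X >= k) for Poisson by direct series summation of the lower tail."""
    lower = sum(exp(-rate) * rate**j / factorial(j) for j in range(k))
    return 1.0 - lower


def bh_stepup_by_hand(pvalues):
    """Textbook BH step-up: sort, scale by n/rank, enforce monotonicity."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        value = min(prev, pvalues[i] * n / rank_from_top)
        adjusted[i] = value
        prev = value
    return adjusted
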