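"""Independent reference computations used only by the test suite.

Each oracle takes a different computational path from the implementation it
checks: dynamic programming instead of closed-form multinomial weights for
the Hardy-Weinberg exact test, exact big-integer tail sums instead of
scipy's hypergeometric survival function, the literal step-up formula for
Benjamini-Hochberg, and direct allele counting for MAF.
"""

from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np


@lru_cache(maxsize=None)
def hwe_weight_table(n: int, n_minor: int) -> dict[int, int]:
    """Exact het-count weights by DP over individuals.

    Each individual's two allele slots consume 0, 1 or 2 minor alleles with
    multiplicity 1, 2, 1 (ordered slots). States track (minor consumed,
    het count); the result counts ordered-slot assignments per het count,
    conditional on the total minor-allele count.
    """
    states: dict[tuple[int, int], int] = {(0, 0): 1}
    for _ in range(n):
        nxt: dict[tuple[int, int], int] = {}
        for (m, h), w in states.items():
            for consume, mult, dh in ((0, 1, 0), (1, 2, 1), (2, 1, 0)):
                if m + consume <= n_minor:
                    key = (m + consume, h + dh)
                    nxt[key] = nxt.get(key, 0) + w * mult
        states = nxt
    return {h: w for (m, h), w in states.items() if m == n_minor}


def hwe_exact_p_oracle(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided (probability-ordering) HWE exact p via the DP enumeration."""
    n = n_hom_major + n_het + n_hom_minor
    n_minor = min(2 * n_hom_major + n_het, 2 * n_hom_minor + n_het)
    if n_minor == 0:
        return 1.0
    weights = hwe_weight_table(n, n_minor)
    w_obs = weights[n_het]
    total = sum(weights.values())
    return float(Fraction(sum(w for w in weights.values() if w <= w_obs), total))


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact integer tail sum."""
    if k <= 0:
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, hi + 1) if n - i <= N - K)
    return num / comb(N, n)


def hypergeom_tails_all_k(N: int, K: int, n: int) -> np.ndarray:
    """Upper-tail p for every k = 0..min(K, n), via exact suffix sums."""
    hi = min(K, n)
    pmf_num = [comb(K, i) * comb(N - K, n - i) if 0 <= n - i <= N - K else 0 for i in range(hi + 1)]
    denom = comb(N, n)
    tails = np.empty(hi + 1)
    acc = 0
    for i in range(hi, -1, -1):
        acc += pmf_num[i]
        tails[i] = acc / denom
    return tails


def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up formula."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def maf_counting_oracle(dosages: np.ndarray) -> float:
    """MAF by explicit allele tallying over called genotypes."""
    alt = 0
    ref = 0
    for d in dosages:
        if d is None or (isinstance(d, float) and np.isnan(d)) or d == -1:
            continue
        alt += int(d)
        ref += 2 - int(d)
    total = alt + ref
    if total == 0:
        raise ValueError("no called genotypes")
    f = alt / total
    return min(f, 1 - f)


def ols_statsmodels_oracle(X: np.ndarray, y: np.ndarray):
    """Coefficients, SEs and t-test p-values from statsmodels OLS."""
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    return fit.params, fit.bse, fit.pvalues
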