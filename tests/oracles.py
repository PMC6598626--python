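"""Independent reference implementations used only to check the package.

These deliberately use different formulations from the production code:
top-down enumeration with explicit gap states for alignment, raw normal
equations for OLS, exact rational Levene-Haldane probabilities for HWE.
"""

import math
import sys
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy import stats


def oracle_glocal_score(q: str, r: str, sc) -> int:
    """Best glocal affine-gap score by memoized top-down path enumeration."""
    m, n = len(q), len(r)
    sys.setrecursionlimit(20000)

    @lru_cache(maxsize=None)
    def best(i, j, state):
        if i == m:
            return 0  # remaining reference is free
        cands = []
        if j < n:
            s = sc.match if q[i] == r[j] else sc.mismatch
            cands.append(s + best(i + 1, j + 1, "M"))
            gap = sc.gap_extend + (sc.gap_open if state != "D" else 0)
            cands.append(gap + best(i, j + 1, "D"))
        gap = sc.gap_extend + (sc.gap_open if state != "I" else 0)
        cands.append(gap + best(i + 1, j, "I"))
        return max(cands)

    result = max(best(0, j0, "S") for j0 in range(n + 1))
    best.cache_clear()
    return result


def oracle_ols(y, X):
    """OLS by raw normal equations: beta, se, t, two-sided p per column."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - p)
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), n - p)
    return beta, se, t, pvals


def oracle_hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p by full enumeration with rational arithmetic."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    if na == 0 or nb == 0:
        return 1.0
    rare = min(na, nb)

    def prob(het):
        hom_r = (rare - het) // 2
        hom_c = (2 * n - rare - het) // 2
        return Fraction(
            math.factorial(n) * 2**het * math.factorial(rare) * math.factorial(2 * n - rare),
            math.factorial(hom_r)
            * math.factorial(het)
            * math.factorial(hom_c)
            * math.factorial(2 * n),
        )

    probs = {het: prob(het) for het in range(rare % 2, rare + 1, 2)}
    p_obs = probs[n_ab]
    return float(min(Fraction(1), sum(p for p in probs.values() if p <= p_obs)))


def random_spanning_tree_weight(vectors: dict, rng: np.random.Generator) -> int:
    """Total Hamming weight of a uniformly grown random spanning tree."""
    names = sorted(vectors)
    in_tree = {names[int(rng.integers(len(names)))]}
    weight = 0
    remaining = [x for x in names if x not in in_tree]
    rng.shuffle(remaining)
    for v in remaining:
        u = sorted(in_tree)[int(rng.integers(len(in_tree)))]
        weight += sum(a != b for a, b in zip(vectors[u], vectors[v]))
        in_tree.add(v)
    return weight
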