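"""Independent oracles used by the tests.

These deliberately avoid the package's code paths: the Mann-Whitney oracle
counts pairs and enumerates group assignments directly instead of using the
rank-sum convolution, and the power oracle is a closed-form large-sample
normal approximation.
"""

import itertools
import math

import numpy as np
from scipy import stats as sps


def u_by_pair_counting(x, y) -> float:
    """U for group x: number of (x, y) pairs with x > y, ties counted half."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def brute_force_p(x, y, alternative="two-sided") -> float:
    """Exact Mann-Whitney p by complete enumeration of group assignments.

    Enumerates all C(n1+n2, n1) ways to label the pooled values as group x
    and tail-counts the observed U. Intended for tie-free pooled samples of
    size <= ~12.
    """
    pooled = list(x) + list(y)
    n1, n = len(x), len(pooled)
    u_obs = u_by_pair_counting(x, y)
    us = []
    for idx in itertools.combinations(range(n), n1):
        chosen = set(idx)
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(n) if i not in chosen]
        us.append(u_by_pair_counting(gx, gy))
    us = np.asarray(us)
    eps = 1e-9
    cdf = float(np.mean(us <= u_obs + eps))
    sf = float(np.mean(us >= u_obs - eps))
    if alternative == "less":
        p = cdf
    elif alternative == "greater":
        p = sf
    else:
        p = 2.0 * min(cdf, sf)
    return min(p, 1.0)


def bh_adjust_by_definition(pvalues):
    """BH adjusted p-values straight from the definition:
    adjusted_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    for pos, i in enumerate(order, start=1):
        adjusted[i] = min(min(p[j] * m / (order.index(j) + 1)
                              for j in order[pos - 1:]), 1.0)
    return adjusted


def normal_shift_power(delta, sigma, n1, n2, alpha=0.05):
    """Large-sample power of the two-sided Mann-Whitney test when group x is
    Normal(mu - delta, sigma^2) against Normal(mu, sigma^2).

    Uses P(X < Y) = Phi(delta / (sigma * sqrt(2))) and the null-variance
    normal approximation of U.
    """
    p_less = sps.norm.cdf(delta / (sigma * math.sqrt(2.0)))
    n = n1 + n2
    mean_shift = n1 * n2 * abs(p_less - 0.5)
    sd0 = math.sqrt(n1 * n2 * (n + 1) / 12.0)
    z_alpha = sps.norm.ppf(1.0 - alpha / 2.0)
    return float(sps.norm.cdf(mean_shift / sd0 - z_alpha))
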