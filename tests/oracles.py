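"""Independent brute-force oracles used only by the tests.

These are written directly from textbook formulas, independent of the
package code paths they check.
"""

import itertools
import math

from scipy.stats import norm


def mh_pooled_or_oracle(cells):
    """Mantel-Haenszel pooled OR, RBG 95% CI and two-sided p from the raw
    textbook expressions; ``cells`` is a list of (a, b, c, d) floats (the
    caller applies any zero-cell correction beforehand)."""
    R = sum(a * d / (a + b + c + d) for a, b, c, d in cells)
    S = sum(b * c / (a + b + c + d) for a, b, c, d in cells)
    or_mh = R / S
    top = mid = bot = 0.0
    for a, b, c, d in cells:
        n = a + b + c + d
        p_i, q_i = (a + d) / n, (b + c) / n
        r_i, s_i = a * d / n, b * c / n
        top += p_i * r_i
        mid += p_i * s_i + q_i * r_i
        bot += q_i * s_i
    var = top / (2 * R**2) + mid / (2 * R * S) + bot / (2 * S**2)
    se = math.sqrt(var)
    z975 = norm.ppf(0.975)
    lo = math.exp(math.log(or_mh) - z975 * se)
    hi = math.exp(math.log(or_mh) + z975 * se)
    p = 2 * (1 - norm.cdf(abs(math.log(or_mh)) / se))
    return or_mh, lo, hi, p


def mann_whitney_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of all
    C(n+m, n) assignments of the pooled (untied) values to the two arms."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires untied values"
    n = len(x)
    values = sorted(pooled)

    def u_stat(sample_x):
        sample_y = [v for v in values if v not in sample_x]
        u = sum(1 for xi in sample_x for yj in sample_y if xi > yj)
        return min(u, len(sample_x) * len(sample_y) - u)

    observed = u_stat(sorted(x))
    count = total = 0
    for combo in itertools.combinations(values, n):
        total += 1
        if u_stat(list(combo)) <= observed:
            count += 1
    return count / total


def bh_oracle(p_values):
    """Benjamini-Hochberg step-up by the definitional sweep."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, p_values[idx] * m / rank)
        q[idx] = val
        prev = val
    return q
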