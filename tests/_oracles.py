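"""Independent brute-force oracles shared by the test modules."""

import itertools


def mw_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of group labelings.

    U for the first group counts pairs (xi > yj) + half-ties; the two-sided
    p doubles the smaller tail of the permutation distribution (capped at 1).
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(first, second):
        u = 0.0
        for a in first:
            for b in second:
                u += (a > b) + 0.5 * (a == b)
        return u

    u_obs = u_stat(x, y)
    us = []
    for ix in itertools.combinations(range(len(pooled)), n1):
        chosen = set(ix)
        first = [pooled[i] for i in ix]
        second = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        us.append(u_stat(first, second))
    lo = sum(u <= u_obs + 1e-12 for u in us) / len(us)
    hi = sum(u >= u_obs - 1e-12 for u in us) / len(us)
    return min(1.0, 2.0 * min(lo, hi))
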