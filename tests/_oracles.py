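"""Independent brute-force oracles used by the test suite."""

from math import comb


def fisher_two_tail_oracle(k: int, m: int, r: int, u: int) -> float:
    """Two-tailed hypergeometric p by exact enumeration.

    Sums P(overlap = j) over every j whose table probability does not
    exceed the observed one; weights are integer products of binomial
    coefficients, so the comparison is exact.
    """
    lo, hi = max(0, r - (u - m)), min(m, r)
    weights = {j: comb(m, j) * comb(u - m, r - j) for j in range(lo, hi + 1)}
    w_obs = weights[k]
    return sum(w for w in weights.values() if w <= w_obs) / comb(u, r)
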