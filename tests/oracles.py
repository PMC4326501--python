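"""Independent brute-force oracles shared by the test suite.

These deliberately avoid ``scipy.stats`` distribution objects: binomial
probabilities start from a log-gamma term and proceed by the pmf ratio
recurrence, so they check the implementation by a different route.
"""

import math


def binom_logpmf(k: int, n: int, p: float) -> float:
    return (
        math.lgamma(n + 1)
        - math.lgamma(k + 1)
        - math.lgamma(n - k + 1)
        + (k * math.log(p) if k else 0.0)
        + ((n - k) * math.log1p(-p) if n - k else 0.0)
    )


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) by direct upward summation from the boundary term."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    term = math.exp(binom_logpmf(k, n, p))
    total = term
    for j in range(k, n):
        term *= (n - j) / (j + 1) * p / (1.0 - p)
        total += term
        if term < total * 1e-17:
            break
    return min(total, 1.0)


def poisson_twosided(a: int, b: int, lib_a: float, lib_b: float) -> float:
    """Exact conditional equal-rates p-value by minimum-likelihood summation.

    The pmf over k = 0..n is built outward from the mode in plain floats
    (terms more than ~300 orders of magnitude below the mode underflow to
    zero, which is far beyond any tolerance used against it).
    """
    n = a + b
    if n == 0:
        return 1.0
    p = lib_a / (lib_a + lib_b)
    q = 1.0 - p
    mode = min(n, max(0, int((n + 1) * p)))
    pmf = [0.0] * (n + 1)
    pmf[mode] = math.exp(binom_logpmf(mode, n, p))
    for k in range(mode, n):
        pmf[k + 1] = pmf[k] * (n - k) / (k + 1) * (p / q)
    for k in range(mode, 0, -1):
        pmf[k - 1] = pmf[k] * k / (n - k + 1) * (q / p)
    cutoff = pmf[a] * (1.0 + 1e-7)
    return min(1.0, sum(v for v in pmf if v <= cutoff))
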