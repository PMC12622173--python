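"""Exact upper-tail probabilities in log space.

Hypergeometric and binomial survival functions evaluated with lgamma plus an
early-terminating series, so p-values far below double underflow (the
regulatory-overlap regime of 1e-76 and beyond) stay representable as log
values. Arguments are canonicalised so symmetric calls return bit-identical
results.
"""

from __future__ import annotations

import math

from scipy.special import gammaln

_LN10 = math.log(10.0)
# stop the series when the next term can no longer move the double sum
_REL_EPS = 1e-17


def log_binom_coeff(n: int, k: int) -> float:
    """ln C(n, k) via lgamma."""
    if k < 0 or k > n:
        return -math.inf
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def _hypergeom_logpmf(i: int, N: int, n1: int, n2: int) -> float:
    return (
        log_binom_coeff(n1, i)
        + log_binom_coeff(N - n1, n2 - i)
        - log_binom_coeff(N, n2)
    )


def log_hypergeom_sf(k: int, N: int, n1: int, n2: int) -> float:
    """ln P(X >= k) for X ~ Hypergeometric(N, n1, n2).

    X is the overlap when n2 items are drawn without replacement from a
    universe of N containing n1 marked items. The function is symmetric in
    (n1, n2) and is evaluated on the canonical ordering min/max so both call
    orders give identical floats (RRHO relies on this for exact transpose
    symmetry).
    """
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, n1={n1}, n2={n2}")
    if n1 > n2:
        n1, n2 = n2, n1
    lo = max(0, n1 + n2 - N)
    hi = n1
    if k <= lo:
        return 0.0
    if k > hi:
        return -math.inf

    mode = ((n1 + 1) * (n2 + 1)) // (N + 2)

    def up_ratio(i: int) -> float:
        # pmf(i+1)/pmf(i)
        return ((n1 - i) * (n2 - i)) / ((i + 1) * (N - n1 - n2 + i + 1))

    def down_ratio(i: int) -> float:
        # pmf(i-1)/pmf(i)
        return (i * (N - n1 - n2 + i)) / ((n1 - i + 1) * (n2 - i + 1))

    if k > mode:
        # terms decay moving up the tail: sum directly
        log0 = _hypergeom_logpmf(k, N, n1, n2)
        total, term, i = 1.0, 1.0, k
        while i < hi:
            term *= up_ratio(i)
            i += 1
            total += term
            if term <= total * _REL_EPS:
                break
        return log0 + math.log(total)

    # below the mode the complement converges instead: P(X>=k) = 1 - P(X<=k-1)
    j = k - 1
    log0 = _hypergeom_logpmf(j, N, n1, n2)
    total, term, i = 1.0, 1.0, j
    while i > lo:
        term *= down_ratio(i)
        i -= 1
        total += term
        if term <= total * _REL_EPS:
            break
    log_lower = log0 + math.log(total)
    if log_lower >= 0.0:
        # lower tail rounded to 1; upper tail is numerically 0 at double precision
        return -math.inf
    return math.log1p(-math.exp(log_lower))


def log_binom_sf(k: int, n: int, p: float) -> float:
    """ln P(X >= k) for X ~ Binomial(n, p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"binomial p out of range: {p}")
    if k <= 0:
        return 0.0
    if k > n:
        return -math.inf
    if p == 0.0:
        return -math.inf
    if p == 1.0:
        return 0.0
    lp, lq = math.log(p), math.log1p(-p)

    def logpmf(i: int) -> float:
        return log_binom_coeff(n, i) + i * lp + (n - i) * lq

    mode = math.floor((n + 1) * p)
    if k > mode:
        log0 = logpmf(k)
        total, term, i = 1.0, 1.0, k
        while i < n:
            term *= ((n - i) * p) / ((i + 1) * (1.0 - p))
            i += 1
            total += term
            if term <= total * _REL_EPS:
                break
        return log0 + math.log(total)

    j = k - 1
    log0 = logpmf(j)
    total, term, i = 1.0, 1.0, j
    while i > 0:
        term *= (i * (1.0 - p)) / ((n - i + 1) * p)
        i -= 1
        total += term
        if term <= total * _REL_EPS:
            break
    log_lower = log0 + math.log(total)
    if log_lower >= 0.0:
        return -math.inf
    return math.log1p(-math.exp(log_lower))


def neg_log10_from_ln(log_p: float) -> float:
    """Convert a natural-log p-value to the -log10 display scale."""
    if log_p == -math.inf:
        return math.inf
    return -log_p / _LN10
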