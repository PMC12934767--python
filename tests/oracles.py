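"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: Fisher/hypergeometric
tails are enumerated with integer combinatorics, the beta-binomial pmf is
evaluated with arbitrary-precision arithmetic (sympy), and Spearman is
computed as rank-then-Pearson.
"""

from __future__ import annotations

import math

import numpy as np


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Point-mass-inclusive two-sided Fisher p by exact tail enumeration.

    Integer hypergeometric weights; tables whose weight is <= the observed
    weight (with a 1e-7 relative tie tolerance, matching the conventional
    floating-point rule) are summed.
    """
    m = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = math.comb(m, col1)
    w_obs = math.comb(row1, a) * math.comb(m - row1, col1 - a)
    lo = max(0, col1 - (m - row1))
    hi = min(row1, col1)
    total = 0
    for k in range(lo, hi + 1):
        w = math.comb(row1, k) * math.comb(m - row1, col1 - k)
        if w <= w_obs + w_obs * 1e-7:
            total += w
    return total / denom


def hypergeom_upper(k: int, m: int, n_target: int, n_query: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M=m, K=n_target, n=n_query), enumerated."""
    denom = math.comb(m, n_query)
    lo = max(k, max(0, n_query - (m - n_target)))
    hi = min(n_target, n_query)
    return sum(
        math.comb(n_target, j) * math.comb(m - n_target, n_query - j)
        for j in range(lo, hi + 1)
    ) / denom


def betabinom_logpmf_highprec(k: int, n: int, mu, rho, digits: int = 50) -> float:
    """Beta-binomial log pmf at (mu, rho) via sympy arbitrary precision."""
    import sympy as sp

    mu = sp.Rational(mu)
    rho = sp.Rational(rho)
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    pmf = sp.binomial(n, k) * sp.beta(k + a, n - k + b) / sp.beta(a, b)
    return float(sp.log(pmf).evalf(digits))


def spearman_bruteforce(x, y) -> float:
    """Spearman rho as Pearson of midranks (ties averaged)."""
    def midrank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def mean_tag_deviation(baseline_psi: float, delta_psi: float) -> float:
    """Closed-form expected |R - 0.5| at a het tag SNP in functional-SNP hets.

    One haplotype includes at ``baseline_psi``, the other at
    ``baseline_psi + delta_psi``; the reference allele lands on either
    haplotype with probability 1/2, so the ratio is b/(2b+d) or (b+d)/(2b+d)
    and |R - 0.5| = d / (2 (2b + d)) either way.
    """
    return delta_psi / (2.0 * (2.0 * baseline_psi + delta_psi))
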