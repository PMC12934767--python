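"""Beta-binomial modelling of allelic read ratios.

Allelic counts at a heterozygous SNP are overdispersed relative to a binomial:
the underlying allelic ratio varies across samples (biology) on top of the
sampling noise set by sequencing depth. The beta-binomial captures both. We use
the mean/intra-class-correlation parameterisation

    alpha = mu * (1 - rho) / rho,    beta = (1 - mu) * (1 - rho) / rho,

where ``mu`` in (0, 1) is the mean allelic ratio and ``rho`` in [0, 1) the
overdispersion; ``rho -> 0`` recovers the binomial. Group differences in
allelic ratio are tested with a likelihood-ratio test comparing a shared
(mu, rho) fit against group-specific fits (chi-square, 2 df).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["BetaBinomialFit", "bb_loglik", "bb_fit", "bb_lrt"]

_EPS_MU = 1e-6
_RHO_MAX = 1.0 - 1e-6
# deterministic multi-start grid; the best grid point seeds one local optimiser
_MU_GRID = np.arange(0.1, 0.95, 0.1)
_RHO_GRID = np.array([0.001, 0.05, 0.2])


@dataclass(frozen=True)
class BetaBinomialFit:
    """Maximum-likelihood fit of a beta-binomial to (ref, total) counts."""

    mu: float
    rho: float
    loglik: float
    n_obs: int
    converged: bool


def _as_counts(counts) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("counts must be a sequence of (ref, total) pairs")
    k, n = arr[:, 0], arr[:, 1]
    if np.any(n <= 0):
        raise ValueError("all totals must be positive")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("ref counts must lie in [0, total]")
    return k, n


def bb_loglik(counts, mu: float, rho: float) -> float:
    """Beta-binomial log-likelihood of (ref, total) pairs at (mu, rho).

    ``rho = 0`` is evaluated as the binomial limit.
    """
    k, n = _as_counts(counts)
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mu must be in (0, 1), got {mu}")
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if rho == 0.0:
        return float(np.sum(stats.binom.logpmf(k, n, mu)))
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    return float(np.sum(stats.betabinom.logpmf(k, n, a, b)))


def _loglik_vec(k: np.ndarray, n: np.ndarray, mu: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Vectorised log-likelihood over parameter points (mu, rho broadcastable)."""
    mu = np.atleast_1d(mu)[:, None]
    rho = np.atleast_1d(rho)[:, None]
    out = np.empty(mu.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(mu.shape[0]):
            r = float(rho[i, 0])
            m = float(mu[i, 0])
            if r == 0.0:
                out[i] = np.sum(stats.binom.logpmf(k, n, m))
            else:
                a = m * (1.0 - r) / r
                b = (1.0 - m) * (1.0 - r) / r
                out[i] = np.sum(stats.betabinom.logpmf(k, n, a, b))
    return out


def bb_fit(counts) -> BetaBinomialFit:
    """Bounded maximum-likelihood estimate of (mu, rho).

    Deterministic: a fixed grid of starting points is scored and the best point
    seeds a single bounded local optimisation. Degenerate data (all counts with
    the same ratio) falls back to the binomial fit at the pooled ratio.
    """
    k, n = _as_counts(counts)
    if len(k) < 2:
        raise ValueError("bb_fit requires at least 2 observations")

    pooled = float(np.clip(np.sum(k) / np.sum(n), _EPS_MU, 1.0 - _EPS_MU))
    ratios = k / n
    if np.allclose(ratios, ratios[0]):
        ll = bb_loglik(np.column_stack([k, n]), pooled, 0.0)
        return BetaBinomialFit(mu=pooled, rho=0.0, loglik=ll, n_obs=len(k), converged=True)

    mu_g, rho_g = np.meshgrid(np.append(_MU_GRID, pooled), _RHO_GRID)
    grid_ll = _loglik_vec(k, n, mu_g.ravel(), rho_g.ravel())
    best = int(np.argmax(grid_ll))
    x0 = np.array([mu_g.ravel()[best], rho_g.ravel()[best]])

    def nll(x):
        m = float(np.clip(x[0], _EPS_MU, 1.0 - _EPS_MU))
        r = float(np.clip(x[1], 0.0, _RHO_MAX))
        return -_loglik_vec(k, n, np.array([m]), np.array([max(r, 1e-12)]))[0]

    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[(_EPS_MU, 1.0 - _EPS_MU), (1e-12, 0.99)],
    )
    mu_hat = float(np.clip(res.x[0], _EPS_MU, 1.0 - _EPS_MU))
    rho_hat = float(np.clip(res.x[1], 0.0, 0.99))
    ll_hat = -float(res.fun)
    # guard: never return worse than the binomial fit at the pooled ratio
    ll_binom = bb_loglik(np.column_stack([k, n]), pooled, 0.0)
    if ll_binom > ll_hat:
        mu_hat, rho_hat, ll_hat = pooled, 0.0, ll_binom
    return BetaBinomialFit(
        mu=mu_hat, rho=rho_hat, loglik=ll_hat, n_obs=len(k), converged=bool(res.success)
    )


def bb_lrt(counts_a, counts_b) -> tuple[float, float]:
    """Likelihood-ratio test for different allelic-ratio distributions.

    Null: both groups share one (mu, rho); alternative: group-specific
    (mu, rho). Statistic ``2 * (ll_a + ll_b - ll_pooled)`` floored at 0,
    referred to chi-square with 2 degrees of freedom.

    Returns (statistic, p_value).
    """
    ka, na = _as_counts(counts_a)
    kb, nb = _as_counts(counts_b)
    fit_a = bb_fit(np.column_stack([ka, na]))
    fit_b = bb_fit(np.column_stack([kb, nb]))
    pooled = np.column_stack([np.concatenate([ka, kb]), np.concatenate([na, nb])])
    fit_0 = bb_fit(pooled)
    stat = max(0.0, 2.0 * (fit_a.loglik + fit_b.loglik - fit_0.loglik))
    p = float(stats.chi2.sf(stat, df=2))
    return stat, p
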