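"""Log-prior densities for epoch-wise log diversification rates.

Three families are supported, all specified on log rates (rates are positive
while the priors live on the whole real line):

* UCLN  — independent, identically distributed log rates,
  ``ln(rate_i) ~ Normal(m0, sigma)``.
* GMRF  — a discretised Brownian motion on log rates,
  ``ln(rate_i) ~ Normal(ln(rate_{i-1}), sigma)``.
* HSMRF — the horseshoe variant with a local scale per increment,
  ``gamma_i ~ halfCauchy(0, 1)``,
  ``ln(rate_i) ~ Normal(ln(rate_{i-1}), sigma * gamma_i)``,
  allowing abrupt jumps while shrinking spurious variation.

The first-epoch (present-day) rate is anchored separately by a Uniform(0,
100) prior on the natural scale (see :func:`anchor_log_prior`); the GMRF and
HSMRF functions below score only the increments.  The global scale sigma
gets a half-Cauchy(0, zeta) hyperprior with zeta calibrated so that the
prior expected number of "effective shifts" (increments exceeding log 2 in
magnitude) over the grid is about log 2 — see
:func:`global_scale_hyperprior_zeta`.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "ucln_log_prior",
    "gmrf_log_prior",
    "hsmrf_log_prior",
    "anchor_log_prior",
    "half_cauchy_logpdf",
    "global_scale_hyperprior_zeta",
    "RECOMMENDED_EPOCH_COUNTS",
]

RECOMMENDED_EPOCH_COUNTS = (4, 10, 20, 50, 100, 200)

_LOG_2_OVER_PI = math.log(2.0 / math.pi)


def _normal_logpdf_sum(x: np.ndarray, mean, sd) -> float:
    x = np.asarray(x, dtype=float)
    z = (x - mean) / sd
    return float(np.sum(-0.5 * z * z - np.log(sd) - 0.5 * math.log(2 * math.pi)))


def half_cauchy_logpdf(x, scale: float = 1.0) -> float:
    """Sum of half-Cauchy(0, scale) log densities; -inf for x <= 0."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x <= 0):
        return -np.inf
    return float(
        np.sum(_LOG_2_OVER_PI - np.log(scale) - np.log1p((x / scale) ** 2))
    )


def anchor_log_prior(log_rate0: float, upper: float = 100.0) -> float:
    """Uniform(0, upper) prior on the natural-scale present-day rate,
    expressed as a density on the log rate (includes the Jacobian)."""
    if log_rate0 >= math.log(upper):
        return -np.inf
    return float(log_rate0 - math.log(upper))


def ucln_log_prior(log_rates, m0: float, sigma: float) -> float:
    """I.i.d. Normal(m0, sigma) over all log rates."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return _normal_logpdf_sum(log_rates, m0, sigma)


def gmrf_log_prior(log_rates, sigma: float) -> float:
    """First-difference Gaussian Markov random field: sum over increments of
    Normal(0, sigma) log densities.  The anchor (first epoch) carries its own
    base prior and is not scored here."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    inc = np.diff(np.asarray(log_rates, dtype=float))
    return _normal_logpdf_sum(inc, 0.0, sigma)


def hsmrf_log_prior(log_rates, sigma: float, gamma) -> float:
    """Horseshoe Markov random field: per-increment local scales gamma_i with
    half-Cauchy(0, 1) priors, increments Normal(0, sigma * gamma_i)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("local scales gamma must be positive")
    inc = np.diff(np.asarray(log_rates, dtype=float))
    if gamma.shape != inc.shape:
        raise ValueError(
            f"need one local scale per increment ({inc.size}), got {gamma.size}"
        )
    lp = half_cauchy_logpdf(gamma, 1.0)
    return lp + _normal_logpdf_sum(inc, 0.0, sigma * gamma)


def _p_shift_given_sigma(sigma: float, threshold: float, horseshoe: bool) -> float:
    """P(|increment| > threshold) for one increment given the global scale."""
    if not horseshoe:
        return 2.0 * stats.norm.sf(threshold / sigma)

    def integrand(g):
        return stats.halfcauchy.pdf(g) * 2.0 * stats.norm.sf(threshold / (sigma * g))

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return val


@lru_cache(maxsize=None)
def global_scale_hyperprior_zeta(
    n_epochs: int, horseshoe: bool = False, expected_shifts: float = math.log(2.0)
) -> float:
    """Scale zeta of the half-Cauchy(0, zeta) hyperprior on the global MRF
    scale sigma, calibrated so that the prior expected number of increments
    larger than log 2 in magnitude equals ``expected_shifts``.

    The expectation integrates over sigma ~ halfCauchy(0, zeta) numerically
    and is solved for zeta by bisection; results are cached per epoch count.
    """
    if n_epochs < 2:
        raise ValueError("need at least two epochs")
    n_inc = n_epochs - 1
    threshold = math.log(2.0)

    def expected(zeta):
        def integrand(s):
            return (
                stats.halfcauchy.pdf(s, scale=zeta)
                * _p_shift_given_sigma(s, threshold, horseshoe)
            )

        val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
        return n_inc * val

    f = lambda z: expected(z) - expected_shifts
    lo, hi = 1e-6, 1.0
    while f(hi) < 0 and hi < 1e4:
        hi *= 4.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-10))


def check_epoch_count(k: int) -> None:
    """Warn (do not fail) when the epoch count is outside the values the
    method was profiled at."""
    if k not in RECOMMENDED_EPOCH_COUNTS:
        import warnings

        warnings.warn(
            f"epoch count {k} is outside the profiled set "
            f"{RECOMMENDED_EPOCH_COUNTS}; proceeding anyway",
            stacklevel=2,
        )
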