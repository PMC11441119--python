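"""Cumulative distribution function of the doubly non-central t-distribution.

T = (Z + delta) / sqrt(W / df) with Z standard normal independent of
W ~ non-central chi-square(df, lam).  Conditioning on the Poisson mixing
variable of W gives the exact mixture representation

    F(x; df, delta, lam)
        = sum_{j>=0} e^{-lam/2} (lam/2)^j / j!
          * F_nct(x * sqrt((df + 2j) / df); df + 2j, delta),

where F_nct is the singly non-central t CDF: given the Poisson index j,
W is a central chi-square with df + 2j degrees of freedom, so
T = T' * sqrt(df / (df + 2j)) with T' singly non-central t on df + 2j
degrees of freedom, whence the rescaled evaluation point.  Each term is a
well-conditioned library call, so the series is evaluated termwise with
the neglected Poisson mass bounded below a truncation tolerance.

In the allocation-bias application ``lam`` is the within-arm spread of
the bias shifts measured in variance units, typically well below 1, so
only a handful of terms contribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special, stats

from .exceptions import ConfigurationError, SeriesConvergenceError

__all__ = [
    "DnctParams",
    "dnct_cdf",
    "dnct_cdf_cached",
    "per_test_rejection_two_sided",
    "DEFAULT_TOL",
    "MAX_TERMS",
]

DEFAULT_TOL = 1e-12
MAX_TERMS = 10_000
_CACHE_SIGFIGS = 12


@dataclass(frozen=True)
class DnctParams:
    """Parameters of a doubly non-central t-distribution."""

    df: float
    delta: float
    lam: float
    tol: float = DEFAULT_TOL

    def __post_init__(self):
        if not self.df > 0:
            raise ConfigurationError(f"df={self.df} must be > 0")
        if not self.lam >= 0:
            raise ConfigurationError(f"lam={self.lam} must be >= 0")
        if not 0 < self.tol < 1e-6:
            raise ConfigurationError(f"tol={self.tol} must be in (0, 1e-6)")


def _poisson_weights(lam2: np.ndarray, n_terms: int) -> np.ndarray:
    """Poisson(lam2) pmf at 0..n_terms-1, via logs to avoid underflow."""
    j = np.arange(n_terms, dtype=float)
    lam2 = lam2[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logw = j * np.log(lam2) - lam2 - special.gammaln(j + 1.0)
    w = np.exp(logw)
    # lam2 == 0: point mass at j = 0
    zero = np.broadcast_to(lam2 == 0, w.shape)
    w = np.where(zero, 0.0, w)
    w[..., 0] = np.where(lam2[..., 0] == 0, 1.0, w[..., 0])
    return w


def dnct_cdf(x, df, delta, lam, *, tol: float = DEFAULT_TOL,
             max_terms: int = MAX_TERMS):
    """P(T <= x) for the doubly non-central t-distribution.

    Parameters broadcast against each other; ``df`` must be a positive
    scalar.  The Poisson mixture over the denominator non-centrality is
    truncated so that the neglected mass is below ``tol``; exceeding
    ``max_terms`` raises :class:`SeriesConvergenceError` with the bound
    actually achieved.  At ``lam = 0`` the result equals the singly
    non-central t CDF, and additionally at ``delta = 0`` the central t CDF.
    """
    if not np.isscalar(df) or not df > 0:
        raise ConfigurationError("df must be a positive scalar")
    if not 0 < tol < 1e-6:
        raise ConfigurationError(f"tol={tol} must be in (0, 1e-6)")
    x, delta, lam = np.broadcast_arrays(
        np.asarray(x, float), np.asarray(delta, float), np.asarray(lam, float)
    )
    if (lam < 0).any():
        raise ConfigurationError("lam must be >= 0")
    scalar = x.ndim == 0
    x, delta, lam = np.atleast_1d(x), np.atleast_1d(delta), np.atleast_1d(lam)

    lam2 = lam / 2.0
    lam2_max = float(lam2.max())
    if lam2_max == 0.0:
        out = np.clip(special.nctdtr(df, delta, x), 0.0, 1.0)
        return float(out[0]) if scalar else out

    # number of terms: Poisson upper tail beyond n_terms-1 must fall below tol
    n_terms = int(stats.poisson.isf(tol, lam2_max)) + 2
    while True:
        if n_terms > max_terms:
            bound = float(stats.poisson.sf(max_terms - 1, lam2_max))
            raise SeriesConvergenceError(
                f"doubly non-central t series needs more than {max_terms} "
                f"terms for lam={2 * lam2_max:g}; achieved truncation bound "
                f"{bound:.3e} > tol={tol:g}",
                achieved_bound=bound,
            )
        w = _poisson_weights(lam2, n_terms)
        neglected = 1.0 - w.sum(axis=-1)
        if (neglected <= tol).all():
            break
        n_terms = min(2 * n_terms, max_terms + 1)

    j = np.arange(n_terms, dtype=float)
    df_j = df + 2.0 * j
    scale = np.sqrt(df_j / df)
    terms = special.nctdtr(df_j, delta[..., None], x[..., None] * scale)
    out = np.clip((w * terms).sum(axis=-1), 0.0, 1.0)
    return float(out[0]) if scalar else out


def _round_sig(v: float, sig: int = _CACHE_SIGFIGS) -> float:
    if v == 0 or not np.isfinite(v):
        return float(v)
    return float(np.format_float_scientific(v, precision=sig - 1))


@lru_cache(maxsize=1_000_000)
def _dnct_cdf_key(x: float, df: float, delta: float, lam: float,
                  tol: float) -> float:
    return dnct_cdf(x, df, delta, lam, tol=tol)


def dnct_cdf_cached(x: float, df: float, delta: float, lam: float,
                    *, tol: float = DEFAULT_TOL) -> float:
    """Memoized scalar CDF.

    Arguments are rounded to 12 significant digits for cache identity:
    across a Monte-Carlo sample of randomization lists the non-centrality
    parameters take few distinct values (they depend on the list only
    through integer counts of bias levels per arm), so repeated
    evaluations collapse onto a small set of keys.
    """
    return _dnct_cdf_key(
        _round_sig(float(x)), float(df), _round_sig(float(delta)),
        _round_sig(float(lam)), float(tol),
    )


def per_test_rejection_two_sided(c_low, df, delta, lam, *,
                                 tol: float = DEFAULT_TOL):
    """Probability that |T| exceeds the two-sided critical value.

    ``c_low`` is the lower-tail central-t quantile t_df(alpha*/2) (< 0
    for alpha* < 1).  By the symmetry Z -> -Z of the numerator,
    P(|T| > -c_low) = F(c_low; df, delta, lam) + F(c_low; df, -delta, lam).
    """
    lo = dnct_cdf(c_low, df, delta, lam, tol=tol)
    hi = dnct_cdf(c_low, df, np.negative(delta), lam, tol=tol)
    return np.clip(lo + hi, 0.0, 1.0)
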