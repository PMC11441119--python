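"""Brute-force simulation oracle for the analytic error-rate formulas.

For a fixed allocation list and bias matrix, patient responses are
simulated from the biased linear model

    X_j = mu_E t_j + mu_C (1 - t_j) + tau_j + eps_j,
    eps_j ~ N_m(0, diag(sigma) corr diag(sigma)) iid,

the actual pooled two-sample t-tests are run, and the rejection
probability of the Sidak or all-or-none decision rule is estimated
empirically.  The oracle is a validation instrument: it shares no code
path with the doubly non-central t formulas it checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .error_rates import TrialDesign, pca_transform
from .exceptions import ConfigurationError, DegenerateSequenceError
from .randomization import AllocationSequence

__all__ = ["OracleConfig", "simulate_responses", "empirical_rate"]

_CHUNK_SCALARS = 2**24  # ~128 MB of float64 per simulated block


@dataclass(frozen=True)
class OracleConfig:
    n_sim: int
    seed: int

    def __post_init__(self):
        if self.n_sim < 1:
            raise ConfigurationError(f"n_sim={self.n_sim} must be >= 1")


def _as_vector(t) -> np.ndarray:
    if isinstance(t, AllocationSequence):
        t = t.t
    return np.asarray(t)


def simulate_responses(t, tau, design: TrialDesign,
                       rng: np.random.Generator) -> np.ndarray:
    """One simulated trial: the N x m response matrix of the biased model."""
    tv = _as_vector(t)
    tau = np.atleast_2d(np.asarray(tau, float))
    mu = np.where(tv[:, None] == 1, design.mu_e[None, :], design.mu_c[None, :])
    chol = np.linalg.cholesky(
        design.covariance + 1e-14 * np.eye(design.m)
    )
    eps = rng.standard_normal((tv.size, design.m)) @ chol.T
    return mu + tau + eps


def _t_statistics(X: np.ndarray, tv: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t statistics per endpoint.

    X has shape (n_sim, N, m); returns (n_sim, m).  The pooled variance
    uses the standard 1/(N-2) scaling, the statistic whose null law the
    doubly non-central t-distribution with N-2 degrees of freedom
    describes.
    """
    is_e = tv == 1
    n_e, n_c = int(is_e.sum()), int((~is_e).sum())
    N = tv.size
    mean_e = X[:, is_e, :].mean(axis=1)
    mean_c = X[:, ~is_e, :].mean(axis=1)
    ss = (((X[:, is_e, :] - mean_e[:, None, :]) ** 2).sum(axis=1)
          + ((X[:, ~is_e, :] - mean_c[:, None, :]) ** 2).sum(axis=1))
    pooled_sd = np.sqrt(ss / (N - 2))
    return np.sqrt(n_e * n_c / N) * (mean_e - mean_c) / pooled_sd


def empirical_rate(t, tau, design: TrialDesign, procedure: str,
                   oracle_config: OracleConfig, *,
                   use_pca: bool | None = None,
                   aon_mode: str = "size") -> float:
    """Empirical error rate of the chosen decision rule.

    Sidak path: fraction of simulated trials in which any endpoint's |t|
    exceeds the two-sided critical value at the adjusted level.

    All-or-none path: the procedure rejects only if every endpoint's t
    exceeds the one-sided critical value at alpha, and its type I error
    is the supremum over the composite null (the union of component
    nulls).  That supremum is attained at the least favourable
    configuration, where every component except the worst one rejects
    almost surely, so with ``aon_mode="size"`` (default) the estimate is
    the maximum over endpoints of the one-sided rejection fractions --
    each component's marginal law at its own null does not depend on the
    other components' means.  ``aon_mode="joint"`` instead returns the
    fraction of trials in which all components reject under the
    simulated configuration itself (the mu_E = mu_C point of the null),
    which is the quantity bounded above by every component's rejection
    fraction.

    ``use_pca`` controls whether the Sidak tests are applied to the
    principal-component transformed responses (the analysis the
    correlated-endpoint formula models).  The default (None) transforms
    exactly when the design has a non-identity correlation; passing
    False keeps the tests on the raw components, which probes whether
    the transformed and untransformed analyses share a per-list FWER.
    """
    if procedure not in ("sidak", "all_or_none"):
        raise ConfigurationError(f"unknown procedure {procedure!r}")
    if aon_mode not in ("size", "joint"):
        raise ConfigurationError(f"unknown aon_mode {aon_mode!r}")
    tv = _as_vector(t)
    tau = np.atleast_2d(np.asarray(tau, float))
    if int(tv.sum()) < 2 or int((1 - tv).sum()) < 2:
        raise DegenerateSequenceError(
            "oracle requires at least two patients per arm"
        )
    if use_pca is None:
        use_pca = procedure == "sidak" and not design.is_independent

    rng = np.random.default_rng(oracle_config.seed)
    N, m = tv.size, design.m
    mu = np.where(tv[:, None] == 1, design.mu_e[None, :], design.mu_c[None, :])
    chol = np.linalg.cholesky(design.covariance + 1e-14 * np.eye(m))
    df = N - 2
    if procedure == "sidak":
        alpha_star = design.alpha_star
        crit = stats.t.ppf(1.0 - alpha_star / 2.0, df)
    else:
        crit = stats.t.ppf(1.0 - design.alpha, df)
    if use_pca:
        pca = pca_transform(design)
        keep = pca.eigenvalues > 1e-10
        A = pca.A[:, keep]

    chunk = max(1, _CHUNK_SCALARS // (N * m))
    n_rej = 0
    n_rej_k = np.zeros(m, dtype=np.int64)
    left = oracle_config.n_sim
    while left > 0:
        n = min(chunk, left)
        eps = rng.standard_normal((n, N, m)) @ chol.T
        X = mu[None, :, :] + tau[None, :, :] + eps
        if use_pca:
            X = X @ A
        S = _t_statistics(X, tv)
        if procedure == "sidak":
            n_rej += int((np.abs(S) > crit).any(axis=1).sum())
        elif aon_mode == "joint":
            n_rej += int((S > crit).all(axis=1).sum())
        else:
            n_rej_k += (S > crit).sum(axis=0)
        left -= n
    if procedure == "all_or_none" and aon_mode == "size":
        return float(n_rej_k.max() / oracle_config.n_sim)
    return n_rej / oracle_config.n_sim
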