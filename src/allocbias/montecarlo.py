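"""Monte-Carlo evaluation of randomization procedures under allocation bias.

For each randomization procedure in a study configuration, ``r``
randomization lists are sampled, the actual biased error rate of every
list is computed analytically (Sidak FWER or all-or-none type I error),
and the per-procedure distribution is summarized by its mean and by the
probability of drawing a list whose error rate stays at or below the
nominal level, P_RP(rate <= alpha).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biasing import BiasPolicy
from .error_rates import TrialDesign, batch_rates
from .exceptions import ConfigurationError
from .randomization import RPSpec, generate_sequences

__all__ = [
    "StudyConfig",
    "ErrorRateResult",
    "run_study",
    "summarize",
    "effect_size_eta",
    "EFFECT_SIZE_BY_N",
    "rp_rng",
    "results_to_frame",
]

#: Standardized effect sizes E_N used for the homogeneous study settings,
#: from which bias effects are derived as eta = nu * E_N.
EFFECT_SIZE_BY_N = {12: 1.795, 32: 1.024, 64: 0.711}

PROCEDURES = ("sidak", "all_or_none")

#: float guard when comparing a rate against the nominal level, so that
#: the unbiased case (rate == alpha exactly, up to float noise) counts
#: as controlled.
_LEVEL_GUARD = 1e-12


@dataclass(frozen=True)
class StudyConfig:
    """One simulation setting: a design, a bias policy, and an RP roster."""

    design: TrialDesign
    policy: BiasPolicy
    rps: tuple
    procedure: str
    r: int
    seed: int
    name: str = ""

    def __post_init__(self):
        if self.procedure not in PROCEDURES:
            raise ConfigurationError(
                f"procedure must be one of {PROCEDURES}, got {self.procedure!r}"
            )
        if self.r < 1:
            raise ConfigurationError(f"r={self.r} must be >= 1")
        if self.policy.m != self.design.m:
            raise ConfigurationError(
                f"policy has {self.policy.m} endpoints, design has {self.design.m}"
            )
        rps = tuple(self.rps)
        for rp in rps:
            rp.validate_for(self.design.N)
        object.__setattr__(self, "rps", rps)


@dataclass(frozen=True)
class ErrorRateResult:
    """Per-procedure Monte-Carlo summary of actual error rates."""

    rp: RPSpec
    rates: np.ndarray = field(repr=False)
    mean: float
    p_controlled: float
    n_degenerate: int


def effect_size_eta(nu: float, effect_sizes) -> BiasPolicy:
    """Bias policy with eta_k = nu * E_k for per-endpoint effect sizes E."""
    return BiasPolicy.from_effect_sizes(nu, effect_sizes)


def summarize(rates, alpha: float) -> tuple[float, float]:
    """Mean rate and fraction of lists with rate <= alpha (+ float guard)."""
    rates = np.asarray(rates, float)
    if rates.size == 0:
        raise ConfigurationError("cannot summarize an empty rate vector")
    return float(rates.mean()), float((rates <= alpha + _LEVEL_GUARD).mean())


def rp_rng(seed: int, rp: RPSpec) -> np.random.Generator:
    """Independent sub-stream for one procedure, derived from the master seed.

    The stream key is a CRC of the procedure label, so a procedure's
    sample does not change when the roster around it changes.
    """
    key = zlib.crc32(rp.label.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def run_study(config: StudyConfig) -> list[ErrorRateResult]:
    """Run the Monte-Carlo study for every procedure in the roster.

    Degenerate lists (an empty arm, possible under complete
    randomization with probability 2^(1-N)) leave the t-test undefined;
    they are excluded from the summaries and counted.
    """
    out = []
    for rp in config.rps:
        rng = rp_rng(config.seed, rp)
        T = generate_sequences(rp, config.design.N, config.r, rng)
        rates = batch_rates(T, config.design, config.policy, config.procedure)
        ok = ~np.isnan(rates)
        mean, p_ctrl = summarize(rates[ok], config.design.alpha)
        out.append(ErrorRateResult(
            rp=rp, rates=rates[ok], mean=mean, p_controlled=p_ctrl,
            n_degenerate=int((~ok).sum()),
        ))
    return out


def results_to_frame(config: StudyConfig,
                     results: list[ErrorRateResult]) -> pd.DataFrame:
    """Tabulate study results, one row per randomization procedure."""
    rows = [{
        "procedure": config.procedure,
        "rp": res.rp.label,
        "N": config.design.N,
        "m": config.design.m,
        "alpha": config.design.alpha,
        "eta": ";".join(f"{e:g}" for e in config.policy.eta),
        "mean_rate": res.mean,
        "p_controlled": res.p_controlled,
        "r": config.r,
        "seed": config.seed,
        "n_degenerate": res.n_degenerate,
    } for res in results]
    return pd.DataFrame(rows)
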