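"""Convergence-strategy biasing policy for multi-endpoint trials.

An unmasked investigator who can track past allocations guesses that the
next patient goes to the currently under-represented arm and selects
patients accordingly: a good responder (response shifted by +eta_k on
endpoint k) when the control arm leads, a bad responder (-eta_k) when
the treatment arm leads, and a neutral patient (no shift) when the arms
are balanced.  The shift of patient j therefore depends only on the
imbalance D_{j-1} observed before their enrolment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .randomization import AllocationSequence, imbalance_trajectory

__all__ = ["BiasPolicy", "bias_signs", "bias_matrix"]


@dataclass(frozen=True)
class BiasPolicy:
    """Endpoint-specific allocation bias effects eta_1..eta_m (response units).

    Each eta_k >= 0 is the magnitude of the response shift a selected
    good/bad responder carries on endpoint k; eta = 0 is the unbiased
    reference.
    """

    eta: np.ndarray = field()

    def __post_init__(self):
        eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        if eta.ndim != 1 or eta.size < 1:
            raise ConfigurationError("eta must be a nonempty vector")
        if not np.isfinite(eta).all() or (eta < 0).any():
            raise ConfigurationError("bias effects eta must be finite and >= 0")
        object.__setattr__(self, "eta", eta)

    @property
    def m(self) -> int:
        return self.eta.size

    @classmethod
    def from_effect_sizes(cls, nu: float, effect_sizes) -> "BiasPolicy":
        """Bias effects as a fraction ``nu`` of per-endpoint effect sizes."""
        if nu < 0:
            raise ConfigurationError(f"nu={nu} must be >= 0")
        e = np.atleast_1d(np.asarray(effect_sizes, dtype=float))
        if (e <= 0).any():
            raise ConfigurationError("effect sizes must be > 0")
        return cls(nu * e)


def bias_signs(t: np.ndarray | AllocationSequence) -> np.ndarray:
    """Responder type of each patient: +1 good, 0 neutral, -1 bad.

    The sign is -sign(D_{j-1}): the investigator expects the next
    allocation to favour the lagging arm, so a leading treatment arm
    (D_{j-1} > 0) attracts a bad responder for what is guessed to be a
    control assignment, and vice versa.
    """
    D = imbalance_trajectory(t)
    return -np.sign(D[:-1]).astype(np.int8)


def bias_matrix(
    t: np.ndarray | AllocationSequence, policy: BiasPolicy
) -> np.ndarray:
    """N x m matrix of response shifts tau_{j,k} in {-eta_k, 0, +eta_k}.

    Row j is the shift vector of patient j; it depends on the allocation
    history only through the imbalance before enrolment, not on the
    patient's own realized assignment.
    """
    s = bias_signs(t)
    return s[:, None].astype(float) * policy.eta[None, :]
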