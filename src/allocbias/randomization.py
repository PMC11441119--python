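"""Allocation-sequence generation for restricted randomization procedures.

Seven procedures commonly used in two-arm 1:1 parallel-group trials are
implemented with their exact sampling distributions:

``CR``
    Complete randomization: every patient is assigned by a fair coin.
``EBC(p)``
    Efron's biased coin: a coin with probability ``p`` favouring the
    currently under-represented arm; fair when arms are balanced.
``BSD(b)``
    Big stick design: fair coin until the group imbalance reaches the
    maximum tolerated imbalance ``b``, then a deterministic assignment
    to the smaller arm.
``CHEN(p, b)``
    Chen's design: Efron's biased coin with a hard imbalance cap ``b``.
``MP(b)``
    Maximal procedure: uniform distribution over all sequences that never
    exceed imbalance ``b`` and end balanced, sampled exactly through a
    path-counting table.
``RAR``
    Random allocation rule: uniform over all sequences with exactly N/2
    treatment assignments.
``PBR(k)``
    Permuted block randomization: independent random-allocation-rule
    blocks of length ``k``.

Sequences are encoded as vectors over {0, 1} with 1 = treatment (E) and
0 = control (C).  The group imbalance after ``j`` patients is
``D_j = N_E(j) - N_C(j)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "RPSpec",
    "AllocationSequence",
    "generate_sequence",
    "generate_sequences",
    "mp_path_counts",
    "mp_transition_probabilities",
    "imbalance_trajectory",
    "RP_NAMES",
]

RP_NAMES = ("CR", "EBC", "BSD", "CHEN", "MP", "RAR", "PBR")

_NEEDS_P = ("EBC", "CHEN")
_NEEDS_B = ("BSD", "CHEN", "MP")
_NEEDS_BLOCK = ("PBR",)


@dataclass(frozen=True)
class RPSpec:
    """A randomization procedure and its parameters.

    Parameters
    ----------
    name : str
        One of ``CR, EBC, BSD, CHEN, MP, RAR, PBR``.
    p : float, optional
        Biased-coin probability in [0.5, 1] (EBC and CHEN only).
    b : int, optional
        Maximum tolerated imbalance, >= 1 (BSD, CHEN and MP only).
    block_size : int, optional
        Even block length >= 2 (PBR only).
    """

    name: str
    p: float | None = None
    b: int | None = None
    block_size: int | None = None

    def __post_init__(self):
        if self.name not in RP_NAMES:
            raise ConfigurationError(
                f"unknown randomization procedure {self.name!r}; "
                f"expected one of {RP_NAMES}"
            )
        if (self.p is not None) != (self.name in _NEEDS_P):
            raise ConfigurationError(
                f"{self.name}: parameter p must be given exactly for EBC and CHEN"
            )
        if (self.b is not None) != (self.name in _NEEDS_B):
            raise ConfigurationError(
                f"{self.name}: parameter b must be given exactly for BSD, CHEN and MP"
            )
        if (self.block_size is not None) != (self.name in _NEEDS_BLOCK):
            raise ConfigurationError(
                f"{self.name}: block_size must be given exactly for PBR"
            )
        if self.p is not None and not 0.5 <= self.p <= 1.0:
            raise ConfigurationError(f"{self.name}: p={self.p} outside [0.5, 1]")
        if self.b is not None and (int(self.b) != self.b or self.b < 1):
            raise ConfigurationError(f"{self.name}: b={self.b} must be an integer >= 1")
        if self.block_size is not None and (
            int(self.block_size) != self.block_size
            or self.block_size < 2
            or self.block_size % 2
        ):
            raise ConfigurationError(
                f"PBR: block_size={self.block_size} must be an even integer >= 2"
            )

    @property
    def label(self) -> str:
        """Conventional display label, e.g. ``CHEN(2,0.67)`` or ``PBR(4)``."""
        if self.name == "EBC":
            return f"EBC({self.p:g})"
        if self.name == "BSD":
            return f"BSD({self.b})"
        if self.name == "CHEN":
            return f"CHEN({self.b},{self.p:g})"
        if self.name == "MP":
            return f"MP({self.b})"
        if self.name == "PBR":
            return f"PBR({self.block_size})"
        return self.name

    def validate_for(self, N: int) -> None:
        """Raise :class:`ConfigurationError` if this procedure cannot produce
        sequences of length ``N``."""
        if N < 2:
            raise ConfigurationError(f"N={N} must be >= 2")
        if self.name in ("RAR", "MP") and N % 2:
            raise ConfigurationError(f"{self.name} requires an even N, got {N}")
        if self.name == "PBR" and N % self.block_size:
            raise ConfigurationError(
                f"PBR({self.block_size}) requires N divisible by the block "
                f"size, got N={N}"
            )


@dataclass(frozen=True)
class AllocationSequence:
    """A realized allocation list t in {0,1}^N (1 = treatment E, 0 = control C)."""

    t: np.ndarray = field()

    def __post_init__(self):
        t = np.asarray(self.t, dtype=np.int8)
        if t.ndim != 1 or t.size < 1:
            raise ConfigurationError("allocation sequence must be a nonempty vector")
        if not np.isin(t, (0, 1)).all():
            raise ConfigurationError("allocation sequence entries must be 0 or 1")
        object.__setattr__(self, "t", t)

    def __len__(self) -> int:
        return self.t.size

    @property
    def n_e(self) -> int:
        return int(self.t.sum())

    @property
    def n_c(self) -> int:
        return int(self.t.size - self.t.sum())

    @property
    def imbalance(self) -> np.ndarray:
        """Trajectory D_0..D_N with D_j = N_E(j) - N_C(j)."""
        return imbalance_trajectory(self.t)

    @property
    def max_imbalance(self) -> int:
        return int(np.abs(self.imbalance).max())


def imbalance_trajectory(t: np.ndarray | AllocationSequence) -> np.ndarray:
    """Imbalance trajectory D_0..D_N of an allocation vector.

    D_j counts treatment minus control assignments among the first j
    patients; D_0 = 0 and consecutive entries differ by exactly one.
    """
    if isinstance(t, AllocationSequence):
        t = t.t
    t = np.asarray(t)
    steps = 2 * t.astype(np.int64) - 1
    out = np.empty(t.size + 1, dtype=np.int64)
    out[0] = 0
    np.cumsum(steps, out=out[1:])
    return out


def mp_path_counts(N: int, b: int) -> np.ndarray:
    """Admissible-completion counts for the maximal procedure.

    Returns an ``(N+1, 2b+1)`` array of exact integer counts (object
    dtype, arbitrary precision) where ``counts[j, d + b]`` is the number
    of +-1 imbalance paths from state ``(j, d)`` to ``(N, 0)`` that keep
    ``|d| <= b`` at every step.  ``counts[0, b]`` is therefore the size
    of the maximal procedure's support.
    """
    if N < 2 or N % 2:
        raise ConfigurationError(f"mp_path_counts requires even N >= 2, got {N}")
    if b < 1:
        raise ConfigurationError(f"mp_path_counts requires b >= 1, got {b}")
    counts = np.zeros((N + 1, 2 * b + 1), dtype=object)
    counts[N, b] = 1
    for j in range(N - 1, -1, -1):
        for di in range(2 * b + 1):
            d = di - b
            c = 0
            if d + 1 <= b:
                c += counts[j + 1, di + 1]
            if d - 1 >= -b:
                c += counts[j + 1, di - 1]
            counts[j, di] = c
    return counts


def mp_transition_probabilities(N: int, b: int) -> np.ndarray:
    """P(next assignment is treatment | step j, imbalance d) for MP(b).

    ``probs[j, d + b]`` is the probability of stepping up (assigning E)
    at state ``(j, d)``, proportional to the number of admissible
    completions through ``(j+1, d+1)``.  States with no admissible
    completion carry probability 0.
    """
    counts = mp_path_counts(N, b)
    probs = np.zeros((N, 2 * b + 1), dtype=float)
    for j in range(N):
        for di in range(2 * b + 1):
            tot = counts[j, di]
            if tot == 0:
                continue
            up = counts[j + 1, di + 1] if di + 1 <= 2 * b else 0
            probs[j, di] = up / tot
    return probs


def _rar_block(r: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """r independent uniform draws of a balanced 0/1 vector of length n."""
    keys = rng.random((r, n))
    order = np.argsort(keys, axis=1, kind="stable")
    out = np.zeros((r, n), dtype=np.int8)
    np.put_along_axis(out, order[:, : n // 2], 1, axis=1)
    return out


def generate_sequences(
    spec: RPSpec, N: int, r: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``r`` independent allocation sequences as an ``(r, N)`` 0/1 array.

    The walk-based procedures (EBC, BSD, CHEN, MP) consume one uniform
    per patient per list; deterministic (forced) assignments ignore the
    drawn uniform so the distribution is exact.
    """
    spec.validate_for(N)
    if r < 1:
        raise ConfigurationError(f"r={r} must be >= 1")

    if spec.name == "CR":
        return (rng.random((r, N)) < 0.5).astype(np.int8)

    if spec.name == "RAR":
        return _rar_block(r, N, rng)

    if spec.name == "PBR":
        k = spec.block_size
        blocks = [_rar_block(r, k, rng) for _ in range(N // k)]
        return np.concatenate(blocks, axis=1)

    # walk-based procedures: vectorized over lists, sequential over patients
    U = rng.random((r, N))
    D = np.zeros(r, dtype=np.int64)
    T = np.empty((r, N), dtype=np.int8)

    if spec.name == "MP":
        probs = mp_transition_probabilities(N, spec.b)
        for j in range(N):
            p_up = probs[j, D + spec.b]
            tj = U[:, j] < p_up
            # forced steps (p_up 0 or 1) are deterministic regardless of U
            tj = np.where(p_up >= 1.0, True, np.where(p_up <= 0.0, False, tj))
            T[:, j] = tj
            D += np.where(tj, 1, -1)
        return T

    p = spec.p if spec.p is not None else 0.5
    b = spec.b  # None for EBC
    for j in range(N):
        p_up = np.where(D == 0, 0.5, np.where(D < 0, p, 1.0 - p))
        if b is not None:
            p_up = np.where(D <= -b, 1.0, np.where(D >= b, 0.0, p_up))
        tj = U[:, j] < p_up
        if b is not None:
            tj = np.where(D <= -b, True, np.where(D >= b, False, tj))
        T[:, j] = tj
        D += np.where(tj, 1, -1)
    return T


def generate_sequence(
    spec: RPSpec, N: int, rng: np.random.Generator
) -> AllocationSequence:
    """Draw one allocation sequence from the exact distribution of ``spec``."""
    return AllocationSequence(generate_sequences(spec, N, 1, rng)[0])
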