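import numpy as np
import pytest

from allocbias import RPSpec

ROSTER = (
    RPSpec("CR"),
    RPSpec("BSD", b=3),
    RPSpec("MP", b=3),
    RPSpec("PBR", block_size=4),
    RPSpec("RAR"),
    RPSpec("EBC", p=0.67),
    RPSpec("CHEN", p=0.67, b=2),
)


@pytest.fixture
def roster():
    """The seven randomization procedures of the simulation study."""
    return ROSTER


@pytest.fixture
def rng():
    return np.random.default_rng(20240930)


def exact_sequence_prob(spec: RPSpec, t: np.ndarray) -> float:
    """Exact probability of one allocation sequence under the transition
    rules of the named procedure, computed directly from the definitions
    (independent of the samplers under test)."""
    from math import comb

    t = np.asarray(t)
    N = t.size
    if spec.name == "RAR":
        return (1.0 / comb(N, N // 2)) if t.sum() == N // 2 else 0.0
    if spec.name == "PBR":
        k = spec.block_size
        prob = 1.0
        for i in range(N // k):
            prob *= exact_sequence_prob(RPSpec("RAR"), t[i * k:(i + 1) * k])
        return prob
    if spec.name == "MP":
        from allocbias import mp_path_counts
        counts = mp_path_counts(N, spec.b)
        D = np.concatenate([[0], np.cumsum(2 * t.astype(int) - 1)])
        if np.abs(D).max() > spec.b or D[-1] != 0:
            return 0.0
        return 1.0 / float(counts[0, spec.b])
    prob = 1.0
    d = 0
    for tj in t:
        if spec.name == "CR":
            p_up = 0.5
        elif spec.name == "EBC":
            p_up = 0.5 if d == 0 else (spec.p if d < 0 else 1 - spec.p)
        elif spec.name == "BSD":
            if d <= -spec.b:
                p_up = 1.0
            elif d >= spec.b:
                p_up = 0.0
            else:
                p_up = 0.5
        elif spec.name == "CHEN":
            if d <= -spec.b:
                p_up = 1.0
            elif d >= spec.b:
                p_up = 0.0
            elif d == 0:
                p_up = 0.5
            else:
                p_up = spec.p if d < 0 else 1 - spec.p
        else:
            raise AssertionError(spec.name)
        prob *= p_up if tj == 1 else 1 - p_up
        d += 1 if tj == 1 else -1
    return prob


def all_sequences(N: int):
    """All 2^N binary sequences of length N."""
    out = ((np.arange(2**N)[:, None] >> np.arange(N)[::-1]) & 1)
    return out.astype(np.int8)
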