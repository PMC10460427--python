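"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def urn_enumeration(k: int, alpha_r: float, tau_r: int) -> dict[tuple, float]:
    """Exact terminal-composition law of the urn by exhaustive enumeration.

    Walks every event sequence of length ``tau_r`` over ``k`` alters and sums
    the urn path probabilities; keys are relative-activity compositions
    (ordered tuples of per-alter event counts).  Independent of the package's
    samplers and closed forms; tractable only for tiny ``k``, ``tau_r``.
    """
    law: dict[tuple, float] = {}
    for seq in product(range(k), repeat=tau_r):
        counts = [0] * k
        prob = 1.0
        for step, alter in enumerate(seq):
            total = k * alpha_r + step
            prob *= (counts[alter] + alpha_r) / total
            counts[alter] += 1
        key = tuple(counts)
        law[key] = law.get(key, 0.0) + prob
    return law
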