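"""Reproducible random-number streams.

Every stochastic operation takes one integer seed; internally, independent
sub-streams are derived with ``numpy.random.SeedSequence(seed, spawn_key=key)``
where ``key`` is a tuple of small integers naming the task (e.g. replicate
index, bootstrap index).  The same top-level seed therefore reproduces the
whole experiment, and any single replicate can be regenerated in isolation.
"""

from __future__ import annotations

import numpy as np


def rng_for(seed, *key: int) -> np.random.Generator:
    """A generator for the sub-task named by ``key`` under ``seed``."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


def child_seed(seed: int, *key: int) -> int:
    """A derived integer seed (< 2**31) for the sub-task named by ``key``."""
    return int(rng_for(seed, *key).integers(0, 2**31 - 1))
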