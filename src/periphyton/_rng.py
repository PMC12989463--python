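"""Seed handling: one master seed, named substreams per analysis stage.

Every stochastic operation in the package takes either an integer seed, a
Generator, or None. Substreams are derived with ``numpy.random.SeedSequence``
spawn keys hashed from stage names, so changing the amount of randomness one
stage consumes never perturbs another stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["as_rng", "substream"]


def as_rng(seed) -> np.random.Generator:
    """Coerce ``seed`` (int, SeedSequence, Generator or None) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def substream(seed, *names) -> np.random.Generator:
    """Derive an independent named substream from an integer master seed.

    Names (strings or ints) are hashed with CRC32 into spawn keys; the same
    (seed, names) pair always yields the same stream.
    """
    keys = [
        zlib.crc32(n.encode()) if isinstance(n, str) else int(n) for n in names
    ]
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2**63))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=keys))
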