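"""Deterministic named random streams.

Every stochastic stage of the pipeline draws from its own child generator,
derived from the master seed plus a tuple of stream names.  Re-running one
stage therefore never perturbs the randomness of another, and the whole run
is a pure function of the master seed.
"""
from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, *names) -> np.random.Generator:
    """Return a Generator for the stream identified by ``names``.

    The spawn key is built from CRC32 hashes of the stream names, so the
    mapping (seed, names) -> bit stream is stable across sessions and
    platforms.
    """
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


def child_seed(seed: int, *names) -> int:
    """A 31-bit integer seed derived from (seed, names)."""
    return int(stream(seed, *names).integers(0, 2**31 - 1))
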