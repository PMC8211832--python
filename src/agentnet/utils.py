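"""Seeding helpers: one global seed fans out to per-component streams."""

from __future__ import annotations

import zlib

import numpy as np


def subseed(seed: int, *keys) -> np.random.SeedSequence:
    """Derive a named, order-stable child seed sequence from a global seed.

    String keys are hashed with crc32 so the mapping is stable across runs
    and processes (unlike Python's salted hash()).
    """
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.SeedSequence(ints)


def rng_from(seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(subseed(seed, *keys))
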