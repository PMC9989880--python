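"""Deterministic random-stream derivation.

All stochastic operations in the package draw from generators derived from a
single integer seed plus a short tag path, so sub-operations are
order-independent: adding or removing one draw site never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *tags: int | str) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a stable tag path.

    String tags are hashed with CRC-32 (stable across runs and platforms);
    integer tags are used directly.  The resulting entropy tuple feeds
    ``numpy.random.default_rng`` (PCG64 via SeedSequence).
    """
    entropy: list[int] = [int(seed) & 0x7FFFFFFF]
    for tag in tags:
        if isinstance(tag, str):
            entropy.append(zlib.crc32(tag.encode("utf-8")))
        else:
            entropy.append(int(tag) & 0xFFFFFFFF)
    return np.random.default_rng(entropy)


def subseed(seed: int, *tags: int | str) -> int:
    """Derive a 31-bit child seed from ``seed`` and a tag path."""
    return int(substream(seed, *tags).integers(0, 2**31 - 1))
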