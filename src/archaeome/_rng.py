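"""Seed-derivation helpers.

All randomness in the package flows through per-stage streams derived from one
master seed, so any stage is independently reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *keys) -> np.random.Generator:
    """Generator for a named sub-stream of the master ``seed``.

    Keys are hashed with CRC32 so the mapping is stable across processes and
    Python versions (unlike the built-in ``hash``).
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(str(k).encode("utf-8")) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy))
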