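"""Deterministic seed fan-out.

A single user-facing seed is expanded into independent per-stage /
per-task seeds via :class:`numpy.random.SeedSequence`, with string tags
hashed through CRC-32 so the derivation is stable across processes and
platforms.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(base: int, *parts: int | str) -> int:
    """Derive a child seed (< 2**31) from a base seed and arbitrary tags."""
    entropy: list[int] = [int(base)]
    for p in parts:
        if isinstance(p, (int, np.integer)):
            entropy.append(int(p))
        else:
            entropy.append(zlib.crc32(str(p).encode("utf-8")))
    state = np.random.SeedSequence(entropy).generate_state(1, np.uint32)[0]
    return int(state) & 0x7FFFFFFF
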