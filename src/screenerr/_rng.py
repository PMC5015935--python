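"""Seed handling.

A single user-facing integer seed is expanded into independent per-stage
substreams by hashing a fixed stage label into the seed sequence. Rerunning
one stage in isolation with the same global seed therefore reproduces its
stream exactly, regardless of what other stages consumed.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return the named random substream of a global integer seed."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0xFFFFFFFF, zlib.crc32(label.encode("utf-8"))])
    )
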