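"""Seed handling: one integer seed, named derived sub-streams.

Every stochastic operation in the package receives a ``numpy.random.Generator``
derived from a single user-facing integer seed and a stage name, never global
state.  Derivation is stable across platforms and runs.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def subseed(seed: int, name: str) -> int:
    """Deterministic 31-bit sub-seed for a named stage."""
    return (zlib.crc32(name.encode("utf-8")) ^ (int(seed) & 0xFFFFFFFF)) & 0x7FFFFFFF


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for a named stage, independent across stage names."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, subseed(seed, name)]))
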