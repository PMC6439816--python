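"""Deterministic named substreams from one global seed.

Every stochastic stage derives its generator as ``substream(seed, name)``:
the same (seed, name) always yields the same stream, and distinct names
yield statistically independent streams, so partial re-runs of a pipeline
reproduce exactly.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def spawn_seed(seed: int, name: str) -> np.random.SeedSequence:
    if seed < 0:
        raise ValueError("seed must be non-negative")
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.SeedSequence([int(seed), tag])


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for the named substream of a global seed."""
    return np.random.default_rng(spawn_seed(seed, name))
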