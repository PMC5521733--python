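"""Deterministic stream splitting for multi-source Monte Carlo runs.

A single master seed must drive every stochastic component while keeping the
streams of distinct uncertainty sources independent: switching one source off
may not change the draws of any other source.  We implement this with numpy
``SeedSequence`` spawn keys.  Each named source gets a stable integer key, and
each (source, replicate) pair gets its own child generator.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["source_key", "stream"]


def source_key(name: str) -> int:
    """Stable 32-bit key for a named stochastic source (CRC32 of the name)."""
    return zlib.crc32(name.encode("utf-8"))


def stream(master_seed: int, source: str, *indices: int) -> np.random.Generator:
    """Child generator for ``source`` (optionally per replicate/index).

    The same (seed, source, indices) triple always yields the same stream,
    and streams for distinct triples are statistically independent.
    """
    key = (source_key(source),) + tuple(int(i) for i in indices)
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=key))
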