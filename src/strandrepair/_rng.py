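"""Seed plumbing: every stochastic operation draws from a labelled substream.

A single integer seed plus a fixed string label yields an independent
``numpy.random.Generator``; the label keeps substreams stable when operations
are added or reordered.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator keyed by (seed, label).

    The label is hashed with CRC32 so the entropy pool is reproducible across
    Python processes (unlike ``hash``).
    """
    tag = zlib.crc32(label.encode("utf-8")) & 0xFFFFFFFF
    return np.random.default_rng([tag, int(seed) & 0x7FFFFFFF])
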