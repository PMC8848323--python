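"""Named random substreams derived from a single integer seed.

Every stochastic component takes a seed and a tuple of stream names; the
same (seed, names) always yields the same generator, and streams with
different names are statistically independent, so e.g. changing the hit
noise stream never changes the simulated genome.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: str) -> np.random.Generator:
    keys = [zlib.crc32(str(n).encode("utf-8")) for n in names]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *keys])


def child_seed(seed: int, *names: str) -> int:
    """A derived integer seed below 2**31, for APIs that take a plain seed."""
    return int(substream(seed, *names).integers(0, 2**31 - 1))
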