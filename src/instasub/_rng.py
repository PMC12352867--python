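"""Named, reproducible random substreams.

Every stochastic stage draws from a stream derived from (global seed, stage
label, ...) so that re-running any stage in isolation reproduces its output
regardless of execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys`` under ``seed``.

    Keys may be strings or integers; strings are hashed with CRC32. The same
    (seed, keys) tuple always yields an identical stream.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
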