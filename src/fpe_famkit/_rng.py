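"""Seed-derived random substreams.

One root seed governs a run; every stochastic stage draws from its own named
substream so that any stage can be reproduced in isolation from the run log.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage ``name`` derived from the root ``seed``.

    The stage name is hashed (CRC-32) into the spawn key, so distinct stages
    get statistically independent streams while the same (seed, name) pair
    always reproduces the same draws.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
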