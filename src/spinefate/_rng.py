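"""Named RNG substreams.

All generators in the package derive their randomness from a single integer
seed through named substreams, so that modules can be re-run independently
while a fixed top-level seed still yields bit-identical output.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The stream key is derived from CRC32 of the joined names, so the mapping
    is stable across sessions and platforms.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    key = zlib.crc32("/".join(names).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
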