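"""Deterministic random-substream derivation.

Every stochastic routine in the package derives its generator from a single
top-level integer seed plus a string label (and optionally further tokens such
as a source-node name), so that independent stages draw from independent
streams and reordering stage execution cannot change any result.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *tokens: object) -> np.random.Generator:
    """Return an rng for ``(seed, *tokens)``.

    Tokens are stringified and CRC32-hashed into the seed sequence entropy, so
    substreams for distinct labels are independent while remaining stable
    across sessions and platforms.
    """
    entropy = [int(seed) & 0xFFFFFFFF]
    entropy.extend(zlib.crc32(str(t).encode("utf-8")) for t in tokens)
    return np.random.default_rng(np.random.SeedSequence(entropy))
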