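"""Deterministic seed derivation.

All randomness in the package flows from one root seed through named
sub-streams, so that toggling one pipeline stage never shifts the draws of
another.  Sub-stream keys are hashed with CRC32 to keep derived entropy
integers well below 2**32.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_rng"]


def _key_to_int(key: object) -> int:
    return zlib.crc32(repr(key).encode("utf-8"))


def substream(root_seed: int, *keys: object) -> np.random.SeedSequence:
    """Derive a named :class:`numpy.random.SeedSequence` from ``root_seed``.

    The same ``(root_seed, *keys)`` tuple always yields the same stream;
    distinct key tuples yield statistically independent streams.
    """
    entropy = [int(root_seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.SeedSequence(entropy)


def child_rng(root_seed: int, *keys: object) -> np.random.Generator:
    """A :class:`numpy.random.Generator` on the named sub-stream."""
    return np.random.default_rng(substream(root_seed, *keys))
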