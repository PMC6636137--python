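"""Seed management.

All randomness in the package flows from a single root seed.  A named
stream is derived with :func:`stream` via ``numpy.random.SeedSequence``
spawn keys, so independent stages (simulation, bootstrap, rendering, ...)
never share or consume each other's random state, and any stage can be
re-run in isolation from the root seed plus its path.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "child_seed"]


def _key_part(part) -> int:
    if isinstance(part, (int, np.integer)):
        if part < 0:
            raise ValueError("stream path integers must be non-negative")
        return int(part)
    # stable 32-bit hash for string path elements
    return zlib.crc32(str(part).encode("utf-8"))


def stream(root_seed: int, *path) -> np.random.Generator:
    """Return the generator for stage ``path`` under ``root_seed``.

    ``path`` elements may be non-negative integers or strings (hashed with
    CRC-32).  The same (root_seed, path) always yields the same generator.
    """
    key = tuple(_key_part(p) for p in path)
    return np.random.default_rng(np.random.SeedSequence(int(root_seed), spawn_key=key))


def child_seed(root_seed: int, *path) -> int:
    """A 31-bit integer seed derived from (root_seed, path)."""
    return int(stream(root_seed, *path).integers(0, 2**31))
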