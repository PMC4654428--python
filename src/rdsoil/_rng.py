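"""Counter-based seed streams.

Every simulator derives one independent generator per logical entity
(group, lane, sample) from a single user seed, so adding an entity never
shifts the draws of the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def _as_int(part) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part)
    if isinstance(part, str):
        return zlib.crc32(part.encode("utf-8"))
    raise TypeError(f"stream key parts must be int or str, got {type(part)!r}")


def stream(seed: int, *key) -> np.random.Generator:
    """Return an independent ``Generator`` for the given seed and key path."""
    spawn_key = tuple(_as_int(p) for p in key)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=spawn_key))
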