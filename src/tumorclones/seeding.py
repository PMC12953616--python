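"""Named-stream random seeding.

All randomness in the package flows from a single integer seed. Independent
streams are derived by hashing a path of human-readable names (and integer
indices) into a :class:`numpy.random.SeedSequence` spawn key, so adding a new
stage to a pipeline never perturbs the draws of existing stages.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "spawn_key"]


def spawn_key(*path: str | int) -> tuple[int, ...]:
    """Map a path of names/indices to a deterministic uint32 spawn key."""
    key = []
    for part in path:
        if isinstance(part, (int, np.integer)):
            if part < 0:
                raise ValueError("integer path components must be non-negative")
            key.append(int(part) & 0xFFFFFFFF)
        else:
            key.append(zlib.crc32(str(part).encode("utf-8")) & 0xFFFFFFFF)
    return tuple(key)


def stream(seed: int, *path: str | int) -> np.random.Generator:
    """Return an independent Generator for the named stream under ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=spawn_key(*path)))
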