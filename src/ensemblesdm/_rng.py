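"""Deterministic named random streams.

A single master seed is fanned out into independent per-(stage, species,
method, repeat, ...) streams by hashing the name tuple into a
``SeedSequence`` spawn key.  Adding a species or method therefore never
perturbs the random draws of any other stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "stream_seed"]


def _key(parts: tuple) -> list[int]:
    out = []
    for p in parts:
        if isinstance(p, (int, np.integer)):
            out.append(int(p) & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(p).encode()))
    return out


def stream(master_seed: int, *names) -> np.random.Generator:
    """Return a Generator for the stream identified by ``names``."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(_key(names)))
    return np.random.default_rng(ss)


def stream_seed(master_seed: int, *names) -> int:
    """A 31-bit integer seed for libraries that take plain ints."""
    return int(stream(master_seed, *names).integers(0, 2**31 - 1))
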