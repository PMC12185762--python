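"""Named, independent random streams derived from one user-facing seed.

Each module draws from its own stream so adding an analysis step never
perturbs the simulation trajectory produced by the same seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for", "child_seed"]


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf8"))


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Deterministic generator for stream ``name`` under global ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _name_key(name)]))


def child_seed(seed: int, name: str, k: int = 0) -> int:
    """A derived integer seed (< 2**31) for interfaces that want a plain int."""
    h = zlib.crc32(f"{name}:{k}".encode("utf8"), int(seed) & 0xFFFFFFFF)
    return int(h % (2**31 - 1))
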