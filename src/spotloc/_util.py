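"""Seed derivation helpers.

Every stochastic step in spotloc draws from a Generator derived from a
global integer seed plus a stable string key (typically the cell id), so
results are reproducible and independent of iteration order or parallel
scheduling.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed_sequence"]


def derive_seed_sequence(seed: int, *keys: object) -> np.random.SeedSequence:
    """Build a SeedSequence from a global seed and stable string keys."""
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(str(k).encode("utf-8")) for k in keys)
    return np.random.SeedSequence(entropy)


def derive_rng(seed: int, *keys: object) -> np.random.Generator:
    """Deterministic per-key random generator (e.g. per cell)."""
    return np.random.default_rng(derive_seed_sequence(seed, *keys))
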