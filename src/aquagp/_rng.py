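"""Named random substreams derived from one root seed.

Every stage (founders / meiosis / traits / noise / subsets / CV folds)
pulls its own generator so stages are independently reproducible and
insensitive to each other's draw counts.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """Generator for the substream identified by ``names`` under ``seed``."""
    key = tuple(
        n if isinstance(n, int) else zlib.crc32(n.encode()) for n in names
    )
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def derive_seed(seed: int, *names: str | int) -> int:
    """A plain integer seed (< 2**31) derived from a named substream."""
    return int(substream(seed, *names).integers(2**31))
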