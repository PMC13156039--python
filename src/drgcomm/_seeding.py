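"""Deterministic per-stage random streams.

A single master seed drives the whole pipeline; each stage derives its own
child stream by hashing the stage name, so adding or reordering stages never
perturbs the randomness of the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic child seed (< 2**31) for a named stage."""
    return (int(master_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Generator seeded from the master seed and the stage name."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) % (2**31), zlib.crc32(stage.encode())])
    )
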