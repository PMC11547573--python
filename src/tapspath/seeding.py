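"""Deterministic per-stage seed derivation from one master seed."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed"]


def derive_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """A reproducible child seed for (master_seed, stage, index), < 2**31.

    Uses a SeedSequence spawn key built from a CRC of the stage name so that
    different stages and indices get statistically independent streams while
    re-runs with the same master seed are bit-identical.
    """
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(zlib.crc32(stage.encode()), int(index))
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
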