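"""Deterministic seed fan-out.

A single user-facing seed is split into independent per-stage child seeds
with a splitmix64 step, so that a stage re-run in isolation sees exactly
the same stream as the same stage inside a full pipeline run.
"""

from __future__ import annotations

import zlib

_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def child_seed(master_seed: int, stage: str) -> int:
    """Derive a stage-specific seed below 2**31 from a master seed.

    Deterministic in (master_seed, stage); distinct stages give
    uncorrelated streams for all practical purposes.
    """
    h = zlib.crc32(stage.encode("utf-8"))
    return _splitmix64((master_seed & _MASK64) ^ (h << 32)) % (2**31)
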