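"""Deterministic per-stage seed derivation.

All randomness in a run flows from one global seed. Each stage derives its
own child seed by hashing the stage name, so adding a stage to a pipeline
never perturbs the random streams of earlier stages.
"""

from __future__ import annotations

import zlib

_MOD = 2**31


def derive_seed(seed: int, stage: str) -> int:
    """Derive a child seed for *stage* from a global *seed*.

    Stable across processes and Python versions (crc32-based, not ``hash``).
    """
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode("utf-8"))) % _MOD
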