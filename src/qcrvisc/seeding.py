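"""Deterministic seed derivation for multi-stage runs.

One global seed is hashed with a stage name to give each stage its own
31-bit seed, so adding or reordering stages never perturbs the random
streams of the stages before them.
"""

from __future__ import annotations

import hashlib

__all__ = ["stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """A stable 31-bit seed derived from ``seed`` and a stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
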