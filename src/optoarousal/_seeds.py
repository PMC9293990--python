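"""Deterministic seed derivation.

Every stochastic stage derives its own substream from a single global
integer seed and a stage name, so adding or reordering one generator never
perturbs the draws of another.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a stage-specific seed below 2**31 from ``(global_seed, stage)``.

    The mapping is a SHA-256 hash of the pair, so it is stable across
    platforms and Python versions (unlike ``hash``).
    """
    h = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def rng_for(global_seed: int, stage: str) -> np.random.Generator:
    """A ``numpy`` Generator seeded for one named stage."""
    return np.random.default_rng(derive_seed(global_seed, stage))
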