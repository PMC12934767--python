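"""Deterministic seed fan-out.

A single master seed is expanded into independent per-operation child seeds by
stable hashing of the operation name, so that adding or reordering stages never
perturbs the random stream of another stage.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MOD = 2**31 - 1


def child_seed(master_seed: int, name: str) -> int:
    """Derive a child seed below 2**31 from a master seed and an operation name."""
    h = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:8], "big") % _MOD


def child_rng(master_seed: int, name: str) -> np.random.Generator:
    """Generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(master_seed, name))
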