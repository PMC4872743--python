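"""Seeding policy shared across the package.

Every stochastic operation draws its seed deterministically from a global
seed plus a short stage tag, so re-running any stage reproduces its output
exactly while distinct stages stay decorrelated.
"""

from __future__ import annotations

import hashlib

_MAX_SEED = 2**31


def derive_seed(global_seed: int, tag: str) -> int:
    """Deterministic child seed below 2**31 for a (global seed, stage tag) pair."""
    digest = hashlib.sha256(f"{global_seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % _MAX_SEED
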