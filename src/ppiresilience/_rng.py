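"""Deterministic, label-keyed random number generation.

Every stochastic stage derives its generator from a global integer seed plus
a tuple of string/integer labels (clone id, scheme, replicate index, ...).
This makes per-clone computations order-independent and reproducible.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed_sequence", "spawn_rng"]


def _as_entropy(part: object) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part) & 0xFFFFFFFFFFFFFFFF
    digest = hashlib.sha256(str(part).encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def derive_seed_sequence(*parts: object) -> np.random.SeedSequence:
    """Build a SeedSequence from a global seed and arbitrary labels."""
    return np.random.SeedSequence([_as_entropy(p) for p in parts])


def spawn_rng(*parts: object) -> np.random.Generator:
    """A fresh Generator keyed by ``parts`` (ints and labels)."""
    return np.random.default_rng(derive_seed_sequence(*parts))
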