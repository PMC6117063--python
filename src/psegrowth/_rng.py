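"""Seed plumbing: one user-facing seed, named child streams per module.

Every stochastic operation takes a ``seed`` (int) or an already-constructed
:class:`numpy.random.Generator`.  Child streams are derived from the seed and
a stable name hash, so the mitotic-coordinate stream, say, does not shift when
the stage-table generator draws a different number of variates.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_rng", "as_rng"]


def _name_key(name: str) -> int:
    digest = hashlib.blake2s(name.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def child_rng(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the stream identified by ``seed`` and ``names``."""
    entropy = [int(seed)] + [_name_key(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def as_rng(seed_or_rng) -> np.random.Generator:
    """Accept either an integer seed or a Generator and return a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(int(seed_or_rng))
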