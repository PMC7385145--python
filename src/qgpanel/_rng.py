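"""Seed plumbing: one global seed, named per-stage substreams.

Every stochastic operation in the package derives its generator from a
(seed, stream-name) pair so that pipeline stages can be re-run in isolation
and still reproduce the end-to-end run bit for bit.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream_seed", "substream"]


def substream_seed(seed: int, name: str) -> int:
    """Derive a deterministic 31-bit child seed for a named substream."""
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def substream(seed: int, name: str) -> np.random.Generator:
    """A ``numpy`` Generator for the named substream of ``seed``."""
    return np.random.default_rng(substream_seed(seed, name))
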