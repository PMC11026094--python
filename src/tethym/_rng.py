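"""Seed plumbing: stable per-task substream seeds below 2**31."""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(base_seed: int, *tokens) -> int:
    """Derive a reproducible substream seed from a base seed and identity
    tokens (order-sensitive), independent of execution order elsewhere."""
    key = "|".join(str(t) for t in tokens)
    h = zlib.crc32(key.encode("utf-8"))
    return int((int(base_seed) ^ h) & 0x7FFFFFFF)


def rng_for(base_seed: int, *tokens) -> np.random.Generator:
    return np.random.default_rng(derive_seed(base_seed, *tokens))
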