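"""Deterministic fan-out of a single pipeline seed into per-stage seeds."""

from __future__ import annotations

import hashlib

import numpy as np

_MOD = 2**31 - 1


def child_seed(seed: int, name: str) -> int:
    """Derive a stable per-stage seed from a global seed and a stage name.

    Stable across processes and Python versions (uses sha256, not hash()),
    so that re-running any single stage reproduces its stream regardless of
    stage order.
    """
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    offset = int.from_bytes(digest[:4], "big")
    return (int(seed) ^ offset) % _MOD


def child_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, name))
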