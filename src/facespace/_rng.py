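"""Seed plumbing: every stochastic call derives its generator from one integer."""

from __future__ import annotations

import hashlib

import numpy as np

_MOD = 2**31 - 1


def derive_seed(seed: int, *labels) -> int:
    """Derive a stable sub-seed < 2**31 from a master seed and a label path.

    Counter-based: hashing (seed, labels) keeps stage seeds independent while
    the whole pipeline stays reproducible from a single integer.
    """
    key = repr((int(seed),) + tuple(labels)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:8], "little") % _MOD


def rng_for(seed: int, *labels) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *labels))
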