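"""Deterministic per-stage random streams.

A single user-facing seed fans out to independent child streams keyed by a
stable stage name, so adding or reordering pipeline stages never perturbs the
randomness of other stages.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage *name* derived from the global *seed*."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _name_key(name)]))


def child_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) for stage *name* derived from *seed*."""
    ss = np.random.SeedSequence([int(seed), _name_key(name)])
    return int(ss.generate_state(1)[0] % (2**31))
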