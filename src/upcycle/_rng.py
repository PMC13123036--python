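"""Named random substreams derived from one master seed.

Every stochastic component of a simulation replicate draws from its own
`numpy` Generator, derived deterministically from the replicate's master
seed and a short stream name.  Adding a new consumer therefore never
perturbs the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def substream(master_seed: int, *names: str | int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``."""
    keys = [(_name_key(n) if isinstance(n, str) else int(n) & 0xFFFFFFFF) for n in names]
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=keys))


def spawn_seed(master_seed: int, *names: str | int) -> int:
    """A plain integer seed (< 2**31) derived from a named substream."""
    return int(substream(master_seed, *names).integers(0, 2**31 - 1))
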