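"""Named random substreams derived from one global seed.

Every stochastic stage of the workflow draws from its own generator so that
re-running a single stage with the same global seed reproduces it bit-for-bit
regardless of what ran before.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent Generator for stage *name* under global *seed*."""
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(_key(name),))
    return np.random.default_rng(ss)


def spawn_seed(seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for code that wants a plain seed."""
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(_key(name),))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF
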