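"""Named random substreams derived from one master seed.

Every stage of the pipeline draws from its own named stream so that a stage
can be re-run in isolation and still produce the same values it would have
produced inside a full run.
"""
from __future__ import annotations

import hashlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator deterministically keyed by ``(seed, name)``.

    The name is hashed into the spawn key of a :class:`numpy.random.SeedSequence`
    so distinct names give statistically independent streams.
    """
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    words = tuple(int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=words))
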