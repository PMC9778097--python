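"""Deterministic named random substreams.

Every randomized step in the toolkit draws from a substream derived from one
root seed plus a short name, so stages are independently reproducible and
adding a new randomized step never perturbs existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _tag_to_int(tag: str) -> int:
    return zlib.crc32(tag.encode("utf-8"))


def substream(seed: int, *tags: str) -> np.random.Generator:
    """Return a Generator for the substream named by ``tags`` under ``seed``."""
    entropy = [int(seed) & 0x7FFFFFFF] + [_tag_to_int(t) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))
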