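"""Seed plumbing: one top-level seed, named substreams per pipeline stage."""

from __future__ import annotations

import zlib
from typing import Union

import numpy as np

RngLike = Union[int, np.random.Generator, None]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from a top-level seed and a stage name."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


def as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
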