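"""Named, reproducible random substreams.

A single top-level seed is split into independent substreams keyed by a
stable name, so that e.g. reference-set sampling, synthetic-data generation
and attack simulations can be replayed independently of one another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "as_rng"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the substream `name` under `seed`.

    The same (seed, name) pair always yields an identical stream; distinct
    names yield statistically independent streams.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an int seed, Generator or None into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
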