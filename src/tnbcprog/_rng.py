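"""Deterministic random-number sub-streams.

Every stochastic stage of the pipeline draws from a named sub-stream of a
single integer master seed, so that (a) one seed fully determines every
output and (b) regenerating one platform or one bootstrap resample never
perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _stream_key(name: str | int) -> int:
    if isinstance(name, int):
        if name < 0:
            raise ValueError("integer stream keys must be non-negative")
        return name
    # stable across processes/platforms, unlike hash()
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, *path: str | int) -> np.random.Generator:
    """Return a generator for the sub-stream identified by ``path``.

    ``substream(seed, "mutation")`` and ``substream(seed, "expression")``
    are statistically independent; ``substream(seed, "bootstrap", b)``
    gives one stream per resample index ``b`` so the number of resamples
    can grow without reshuffling earlier ones.
    """
    keys = tuple(_stream_key(p) for p in path)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=keys))
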