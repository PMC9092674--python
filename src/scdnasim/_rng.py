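"""Hierarchical random-stream derivation.

One global seed drives the whole simulation.  Every simulator (and every
cell within a simulator) gets its own independent Generator derived from
``(seed, stream-name[, cell-index])`` via :class:`numpy.random.SeedSequence`
spawn keys, so enlarging a batch never reshuffles the draws of cells that
already existed.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, stream: str, cell: int | None = None) -> np.random.Generator:
    """Return a Generator for an independent named stream.

    Parameters
    ----------
    seed : int
        The global simulation seed.
    stream : str
        Stable stream name, e.g. ``"snp/batch"`` or ``"reads"``.
    cell : int, optional
        Cell index for per-cell streams.
    """
    key: tuple[int, ...] = (zlib.crc32(stream.encode("utf-8")),)
    if cell is not None:
        key = key + (int(cell),)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=key)
    return np.random.default_rng(ss)
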