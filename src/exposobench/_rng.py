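"""Deterministic seed derivation.

Every stochastic component takes a ``seed`` and derives an independent
substream from it via :class:`numpy.random.SeedSequence`, keyed by a
hierarchical path (e.g. ``(master, scenario, run)``).  Results are therefore
reproducible and independent of execution order or worker count.
"""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def _as_entropy(key: tuple) -> list[int]:
    out = []
    for part in key:
        if isinstance(part, str):
            out.append(zlib.crc32(part.encode("utf-8")))
        elif isinstance(part, (int, np.integer)):
            out.append(int(part) & 0xFFFFFFFF)
        else:
            raise TypeError(f"seed key parts must be int or str, got {part!r}")
    return out


def seed_sequence(master: int, *key) -> np.random.SeedSequence:
    """SeedSequence for the substream identified by ``(master, *key)``."""
    return np.random.SeedSequence([int(master)] + _as_entropy(key))


def substream(master: int, *key) -> np.random.Generator:
    """Independent Generator for the substream identified by ``(master, *key)``."""
    return np.random.default_rng(seed_sequence(master, *key))


def child_seed(master: int, *key) -> int:
    """A plain integer seed (< 2**31) derived from ``(master, *key)``.

    For third-party APIs that take an int ``random_state``.
    """
    return int(seed_sequence(master, *key).generate_state(1)[0] % MAX_SEED)
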