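"""Seed plumbing: one global integer seed, split into per-operation streams.

Each stage derives its own `numpy` Generator from the global seed plus a
string label, so stages can be re-run independently without consuming each
other's draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, *labels: str | int) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a sequence of labels."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = [int(seed) & 0x7FFFFFFF]
    for lab in labels:
        if isinstance(lab, (int, np.integer)):
            key.append(int(lab) & 0xFFFFFFFF)
        else:
            key.append(zlib.crc32(str(lab).encode()))
    return np.random.default_rng(np.random.SeedSequence(key))
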