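"""Deterministic named random substreams.

All randomness in the package flows from one integer seed.  Each stage
derives an independent generator from that seed plus a chain of string
labels, so re-running any stage in isolation reproduces its output.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *labels: str | int) -> np.random.Generator:
    """Return a Generator for the substream named by ``labels`` under ``seed``."""
    key = tuple(
        zlib.crc32(str(lab).encode("utf8")) if isinstance(lab, str) else int(lab)
        for lab in labels
    )
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
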