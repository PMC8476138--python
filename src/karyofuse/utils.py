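"""Seeding and small shared helpers."""

from __future__ import annotations

import hashlib

import numpy as np


def substream(seed: int, label: str) -> np.random.Generator:
    """A named, reproducible random substream derived from one master seed.

    Each pipeline stage draws from its own substream so that toggling one
    stage does not shift the realizations of any other.
    """
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    child = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(child)
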