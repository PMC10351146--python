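"""Deterministic seed derivation.

Every source of randomness in a run is a named stream derived from the
master seed, so adding a scenario or metric never perturbs the draws of
another. Streams are labelled hierarchically, e.g.
``seed_stream(master, "rep", 3, "scenario", "VR1 Base", "ocs")``.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["seed_stream", "rng_for"]


def seed_stream(master: int, *labels) -> int:
    """Derive a child seed (< 2**31) from a master seed and a label path.

    The derivation is a SHA-256 hash of the master seed and the repr of
    each label, so it is deterministic, collision-resistant and stable
    across platforms and sessions.
    """
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for lab in labels:
        h.update(b"\x1f")
        h.update(repr(lab).encode())
    return int.from_bytes(h.digest()[:8], "big") % (2**31)


def rng_for(master: int, *labels) -> np.random.Generator:
    """A NumPy Generator seeded from :func:`seed_stream`."""
    return np.random.default_rng(seed_stream(master, *labels))
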