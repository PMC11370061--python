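"""Named substreams fanned out from one global seed.

Every stage derives its randomness from ``substream(seed, "stage-name")`` so
changing the number of draws in one stage never perturbs another.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(seed: int, name: str) -> int:
    """Derive a deterministic 31-bit child seed from (seed, name)."""
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def substream(seed: int, name: str) -> np.random.Generator:
    """A Generator seeded by the named substream of ``seed``."""
    return np.random.default_rng(substream_seed(seed, name))
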