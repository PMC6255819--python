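"""Deterministic seed fan-out.

One hash scheme serves the whole package: a child seed is the first word of
``numpy.random.SeedSequence([master, *key]).generate_state(1)``, reduced mod
2**31.  SeedSequence's mixing function is specified by numpy and stable
across platforms and numpy versions, which makes every derived stream
reproducible from a single master seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_seed", "child_rng"]

_MOD = 2**31


def child_seed(master: int, *key: int) -> int:
    """Derive a deterministic child seed from a master seed and an integer key path."""
    entropy = [int(master) & 0xFFFFFFFF, *(int(k) & 0xFFFFFFFF for k in key)]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0]) % _MOD


def child_rng(master: int, *key: int) -> np.random.Generator:
    """A Generator seeded with :func:`child_seed`."""
    return np.random.default_rng(child_seed(master, *key))
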