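"""Counter-based seed derivation.

A single master seed deterministically spawns independent child seeds for
every (repetition, fold, bootstrap, ...) coordinate, so runs are reproducible
and individual sub-computations are independent of execution order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(*keys: int) -> int:
    """A 31-bit integer seed derived from a tuple of integer coordinates."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def child_rng(*keys: int) -> np.random.Generator:
    """A Generator seeded from a tuple of integer coordinates."""
    return np.random.default_rng(np.random.SeedSequence(list(keys)))
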