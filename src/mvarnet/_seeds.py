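"""Counter-based seed derivation.

Every stochastic routine takes an integer seed and derives independent
substreams with ``numpy.random.SeedSequence([seed, *counters])``.  Substream
k of a master seed is therefore reproducible on its own, independent of how
many sibling streams were drawn before it (needed for order-independent
surrogate ensembles and parallel sweeps).
"""

from __future__ import annotations

import numpy as np


def rng_from(seed: int, *counters: int) -> np.random.Generator:
    """Generator for substream ``counters`` of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, counters)]))


def child_seed(seed: int, *counters: int) -> int:
    """A plain integer seed (< 2**31) for substream ``counters`` of ``seed``."""
    ss = np.random.SeedSequence([int(seed), *map(int, counters)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
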