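"""Shared seed plumbing.

Every stochastic operation takes an explicit ``seed`` that may be an int,
``None``, or a ``numpy.random.SeedSequence`` spawned by a caller higher up
the pipeline; no hidden global random state anywhere.
"""

from __future__ import annotations

import numpy as np


def spawn_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` independent child seeds from ``seed``."""
    if isinstance(seed, np.random.SeedSequence):
        return seed.spawn(n)
    return np.random.SeedSequence(seed).spawn(n)
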