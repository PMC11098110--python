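"""Seed management: one top-level seed, documented per-replicate children.

Replicate ``k`` of a run with top-level seed ``s`` uses the generator
``default_rng(SeedSequence((s, k)))``.  The scheme is a pure function of
``(s, k)``, so any single replicate can be reproduced in isolation.
"""

from __future__ import annotations

import numpy as np


def child_rng(seed: int, k: int) -> np.random.Generator:
    """Independent generator for replicate ``k`` under top-level ``seed``."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(k))))
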