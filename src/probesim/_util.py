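"""Small shared numerics: nearest-rank percentiles and seed derivation."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np


def nearest_rank_percentile(values: Sequence[float] | np.ndarray, p: float) -> float:
    """Nearest-rank (ceiling) percentile of ``values``.

    The p-th percentile is the value at 1-based rank ``ceil(p/100 * n)`` in
    ascending order (rank clamped to [1, n]).  This is the classical textbook
    definition and returns an element of the sample, which keeps reported
    limits reproducible integers when the data are integers.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    if not 0 < p <= 100:
        raise ValueError(f"percentile must be in (0, 100], got {p}")
    rank = min(max(int(math.ceil(p / 100.0 * n)), 1), n)
    return float(arr[rank - 1])


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
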