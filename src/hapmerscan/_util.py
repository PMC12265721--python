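"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np


def max_consecutive_true(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    if mask.size == 0:
        return 0
    m = np.asarray(mask, dtype=bool)
    padded = np.concatenate(([False], m, [False])).astype(np.int8)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    if starts.size == 0:
        return 0
    return int((ends - starts).max())


def true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of maximal True runs."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    padded = np.concatenate(([False], m, [False])).astype(np.int8)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))
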