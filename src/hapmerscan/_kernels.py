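"""Compiled kernels for k-mer code set algebra and membership.

Whole-assembly k-mer work manipulates tens of millions of uint64 codes;
repeated binary search over such arrays is latency-bound, so membership
probes go through a linear-probing open-addressing hash table (load factor
<= 0.5) and set algebra over sorted unique code arrays uses two-pointer
merges.  All kernels are deterministic.
"""

from __future__ import annotations

import numba as nb
import numpy as np

# canonical codes occupy at most 62 bits (k <= 31), so all-ones is free
EMPTY = np.uint64(0xFFFFFFFFFFFFFFFF)


@nb.njit(inline="always", cache=True)
def _mix(x):  # pragma: no cover
    # splitmix64 finalizer: avalanches the 2-bit-packed codes
    x = x ^ (x >> np.uint64(30))
    x = x * np.uint64(0xBF58476D1CE4E5B9)
    x = x ^ (x >> np.uint64(27))
    x = x * np.uint64(0x94D049BB133111EB)
    x = x ^ (x >> np.uint64(31))
    return x


@nb.njit(cache=True)
def hash_build(keys):  # pragma: no cover
    n = keys.size
    size = 2
    while size < 2 * (n + 1):
        size <<= 1
    table = np.full(size, EMPTY, np.uint64)
    mask = np.uint64(size - 1)
    one = np.uint64(1)
    for i in range(n):
        key = keys[i]
        h = _mix(key) & mask
        while True:
            v = table[h]
            if v == EMPTY:
                table[h] = key
                break
            if v == key:
                break
            h = (h + one) & mask
    return table


@nb.njit(cache=True)
def hash_query(table, queries):  # pragma: no cover
    out = np.zeros(queries.size, np.bool_)
    mask = np.uint64(table.size - 1)
    one = np.uint64(1)
    for i in range(queries.size):
        q = queries[i]
        h = _mix(q) & mask
        while True:
            v = table[h]
            if v == EMPTY:
                break
            if v == q:
                out[i] = True
                break
            h = (h + one) & mask
    return out


@nb.njit(cache=True)
def setdiff_sorted(a, b):  # pragma: no cover
    """a \\ b for sorted unique uint64 arrays; result sorted unique."""
    out = np.empty(a.size, np.uint64)
    i = j = n = 0
    while i < a.size:
        v = a[i]
        while j < b.size and b[j] < v:
            j += 1
        if j >= b.size or b[j] != v:
            out[n] = v
            n += 1
        i += 1
    return out[:n]


@nb.njit(cache=True)
def intersect_count_sorted(a, b):  # pragma: no cover
    """|a ∩ b| for sorted unique uint64 arrays."""
    i = j = n = 0
    while i < a.size and j < b.size:
        if a[i] < b[j]:
            i += 1
        elif b[j] < a[i]:
            j += 1
        else:
            n += 1
            i += 1
            j += 1
    return n


def sorted_unique_counts(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(unique sorted values, counts) — sort plus boundary detection.

    Equivalent to ``np.unique(values, return_counts=True)`` but built on
    the much faster plain sort.
    """
    if values.size == 0:
        return values.astype(np.uint64, copy=True), np.empty(0, dtype=np.int64)
    s = np.sort(values)
    edge = np.empty(s.size, dtype=bool)
    edge[0] = True
    np.not_equal(s[1:], s[:-1], out=edge[1:])
    idx = np.flatnonzero(edge)
    counts = np.diff(np.append(idx, s.size)).astype(np.int64)
    return s[idx], counts


def sorted_unique(values: np.ndarray, in_place: bool = False) -> np.ndarray:
    """Sorted distinct values; ``in_place`` sorts the caller's array to
    avoid a copy when it is already a throwaway buffer."""
    if values.size == 0:
        return values.astype(np.uint64, copy=True)
    if in_place:
        values.sort()
        s = values
    else:
        s = np.sort(values)
    edge = np.empty(s.size, dtype=bool)
    edge[0] = True
    np.not_equal(s[1:], s[:-1], out=edge[1:])
    if edge.all():
        return s
    return s[edge]


def member_mask(queries: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Hash-set membership of each query code (table from ``hash_build``)."""
    if queries.size == 0:
        return np.zeros(0, dtype=bool)
    return hash_query(table, queries)
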