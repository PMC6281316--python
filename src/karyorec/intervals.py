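"""Closed-interval arithmetic on 1-based inclusive genomic intervals.

All functions take and return ``(N, 2)`` integer arrays of ``[start, end]``
pairs, 1-based and inclusive at both ends (the package-internal coordinate
convention; BED conversion happens only at the I/O boundary).
"""

from __future__ import annotations

import numpy as np


def as_interval_array(intervals) -> np.ndarray:
    arr = np.asarray(intervals, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intervals must be an (N, 2) array of [start, end]")
    if (arr[:, 0] > arr[:, 1]).any():
        raise ValueError("interval start > end")
    return arr


def merge(intervals) -> np.ndarray:
    """Merge overlapping or bookended (adjacent) closed intervals."""
    arr = as_interval_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = [arr[0].copy()]
    for s, e in arr[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out, dtype=np.int64)


def total_length(intervals) -> int:
    arr = merge(intervals)
    if len(arr) == 0:
        return 0
    return int((arr[:, 1] - arr[:, 0] + 1).sum())


def intersect(a, b) -> np.ndarray:
    """Intersection of two closed interval sets (each merged first)."""
    a = merge(a)
    b = merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(out, dtype=np.int64)


def contains(intervals, positions) -> np.ndarray:
    """Boolean mask: which 1-based positions fall inside the interval set."""
    arr = merge(intervals)
    pos = np.asarray(positions, dtype=np.int64)
    if len(arr) == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(arr[:, 0], pos, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(pos.shape, dtype=bool)
    inside[ok] = pos[ok] <= arr[idx[ok], 1]
    return inside
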