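"""Small interval arithmetic helpers (0-based, half-open) used throughout.

These operate on plain (start, end) integer arrays per chromosome; feature
tables carry chrom/strand/kind metadata around them.
"""

from __future__ import annotations

import numpy as np


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Union of possibly-overlapping intervals, returned sorted and disjoint."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def total_length(starts, ends) -> int:
    s, e = merge_intervals(starts, ends)
    return int((e - s).sum())


def overlap_with_window(starts, ends, w_start: int, w_end: int) -> int:
    """Total bp of the merged intervals falling inside [w_start, w_end)."""
    s, e = merge_intervals(starts, ends)
    if s.size == 0:
        return 0
    clip_s = np.maximum(s, w_start)
    clip_e = np.minimum(e, w_end)
    return int(np.maximum(clip_e - clip_s, 0).sum())


def complement_intervals(starts, ends, chrom_length: int) -> tuple[np.ndarray, np.ndarray]:
    """Gaps of [0, chrom_length) not covered by the (merged) intervals."""
    s, e = merge_intervals(starts, ends)
    bounds_s = np.concatenate(([0], e))
    bounds_e = np.concatenate((s, [chrom_length]))
    keep = bounds_e > bounds_s
    return bounds_s[keep], bounds_e[keep]


def intersect_lengths(a_starts, a_ends, b_starts, b_ends) -> int:
    """Total bp in the intersection of two interval sets (each merged first)."""
    a_s, a_e = merge_intervals(a_starts, a_ends)
    b_s, b_e = merge_intervals(b_starts, b_ends)
    total = 0
    i = j = 0
    while i < a_s.size and j < b_s.size:
        lo = max(a_s[i], b_s[j])
        hi = min(a_e[i], b_e[j])
        if hi > lo:
            total += hi - lo
        if a_e[i] < b_e[j]:
            i += 1
        else:
            j += 1
    return int(total)
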