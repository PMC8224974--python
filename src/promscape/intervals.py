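"""Sorted-array interval arithmetic used throughout the package.

Intervals are 0-based half-open.  Collections are represented per
chromosome as parallel numpy arrays of starts and ends; overlap queries
against a *merged* target set reduce to a single ``searchsorted``, which
keeps the permutation loop fully vectorised.
"""

from __future__ import annotations

from typing import Dict, Iterable, Tuple

import numpy as np

ChromArrays = Dict[str, Tuple[np.ndarray, np.ndarray]]


def to_chrom_arrays(intervals: Iterable) -> ChromArrays:
    """Group objects with .chrom/.start/.end into per-chromosome sorted arrays."""
    by_chrom: Dict[str, list] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: ChromArrays = {}
    for chrom, pairs in by_chrom.items():
        arr = np.asarray(sorted(pairs), dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def merge_arrays(starts: np.ndarray, ends: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping sorted intervals into disjoint ones.

    Abutting intervals ([0,10) and [10,20)) are NOT merged: only ≥1 bp
    overlap joins them, matching the package-wide overlap definition.
    """
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    # running maximum of ends defines merged blocks
    keep = np.ones(len(s), dtype=bool)
    run_end = np.maximum.accumulate(e)
    keep[1:] = s[1:] >= run_end[:-1]
    block = np.cumsum(keep) - 1
    m_starts = s[keep]
    m_ends = np.zeros_like(m_starts)
    np.maximum.at(m_ends, block, e)
    return m_starts, m_ends


def merge_chrom_arrays(arrays: ChromArrays) -> ChromArrays:
    return {c: merge_arrays(s, e) for c, (s, e) in arrays.items()}


def overlaps_any(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    t_starts: np.ndarray,
    t_ends: np.ndarray,
) -> np.ndarray:
    """Boolean array: does each query overlap (≥1 bp) any merged target?

    Targets must be disjoint and sorted by start (see merge_arrays).
    """
    if len(t_starts) == 0 or len(q_starts) == 0:
        return np.zeros(len(q_starts), dtype=bool)
    idx = np.searchsorted(t_starts, q_ends, side="left") - 1
    hit = idx >= 0
    hit[hit] = t_ends[idx[hit]] > q_starts[hit]
    return hit


def count_queries_overlapping(queries: ChromArrays, targets: ChromArrays) -> int:
    """Number of query intervals overlapping ≥1 target interval."""
    merged = merge_chrom_arrays(targets)
    total = 0
    for chrom, (qs, qe) in queries.items():
        if chrom not in merged:
            continue
        ts, te = merged[chrom]
        total += int(overlaps_any(qs, qe, ts, te).sum())
    return total
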