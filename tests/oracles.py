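"""Independent brute-force oracles used by the test suite and acceptance checks.

These deliberately avoid the package's sweep/searchsorted code paths:
overlap is tested all-pairs, components are found by union-find, and
neighbor classes come from a direct rule table.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple


def _overlap(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def consensus_oracle(
    replicate_peaks: Sequence[Sequence[Tuple[str, int, int]]]
) -> List[Tuple[str, int, int]]:
    """Connected components of the all-pairs overlap graph; emit the union
    span of every component containing at least one peak from each replicate."""
    items = []  # (chrom, start, end, rep)
    for r, rep in enumerate(replicate_peaks):
        for chrom, s, e in rep:
            items.append((chrom, s, e, r))
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            if items[i][0] == items[j][0] and _overlap(items[i][1:3], items[j][1:3]):
                union(i, j)

    comps: Dict[int, List[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    n_rep = len(replicate_peaks)
    out = []
    for members in comps.values():
        reps = {items[i][3] for i in members}
        if len(reps) == n_rep:
            chrom = items[members[0]][0]
            out.append(
                (chrom, min(items[i][1] for i in members),
                 max(items[i][2] for i in members))
            )
    return sorted(out)


def neighbor_class_oracle(
    query_strand: str,
    neighbors: Sequence[Tuple[int, str]],
    distance: int = 1000,
) -> str:
    """Direct rule-table neighbor classification.

    ``neighbors`` are (signed TSS offset from the query TSS in genome
    coordinates, strand).  Precedence: multiple nearby > bidirectional >
    same-strand upstream > none; 'upstream' is against the query's
    orientation, strictly nonzero, distance <= `distance`.
    """
    within = [(off, s) for off, s in neighbors if abs(off) <= distance]
    if len(within) >= 2:
        return "multiple_nearby"

    def is_upstream(off: int) -> bool:
        if query_strand == "+":
            return -distance <= off < 0
        return 0 < off <= distance

    for off, s in within:
        if s != query_strand and is_upstream(off):
            return "bidirectional"
    for off, s in within:
        if s == query_strand and is_upstream(off):
            return "same_strand_nearby"
    return "none"
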