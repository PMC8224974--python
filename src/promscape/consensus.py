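"""Per-DBP consensus peaks across replicates and reproducibility filtering.

A consensus peak is the union span of a connected component of the
replicate-peak overlap graph (edge = ≥1 bp overlap) that contains at least
one peak from EVERY replicate.  Components missing any replicate emit
nothing, so a replicate with zero peaks makes the whole DBP unreproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from promscape.genomic_io import GenomeAssembly, GenomicInterval, Peak


@dataclass
class ConsensusPeakSet:
    """Sorted, non-overlapping consensus intervals for one DBP."""

    dbp: str
    intervals: List[GenomicInterval]
    n_replicates: int

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("consensus requires >= 2 replicates")

    @property
    def n_peaks(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class DbpFilterReport:
    dbp: str
    n_consensus_peaks: int
    kept: bool
    reason: str  # ok | no_reproducible_peaks | below_min_peaks

    def __post_init__(self):
        if self.kept != (self.reason == "ok"):
            raise ValueError("kept flag must match reason")


def filter_canonical(
    peaks: Sequence[Peak], genome: GenomeAssembly
) -> Tuple[List[Peak], int]:
    """Keep peaks on canonical chromosomes; return (kept, n_removed)."""
    kept = [p for p in peaks if p.chrom in genome.canonical]
    return kept, len(peaks) - len(kept)


def build_consensus(
    replicate_peaks: Sequence[Sequence[Peak]], dbp: Optional[str] = None
) -> ConsensusPeakSet:
    """Merge replicate peak calls into consensus peaks.

    Components are found by a per-chromosome sweep: intervals sorted by
    start belong to one component while each next start precedes the
    running maximum end (so transitive chains A–B–C join even when A and C
    do not touch).  The result is independent of replicate order and of
    peak order within replicates.
    """
    n_rep = len(replicate_peaks)
    if n_rep < 2:
        raise ValueError("need at least 2 replicates to build consensus")
    if dbp is None:
        for rep in replicate_peaks:
            if rep:
                dbp = rep[0].dbp
                break
        else:
            dbp = "unknown"

    # any empty replicate => nothing can satisfy the all-replicates rule
    if any(len(rep) == 0 for rep in replicate_peaks):
        return ConsensusPeakSet(dbp, [], n_rep)

    events: Dict[str, List[Tuple[int, int, int]]] = {}
    for r, rep in enumerate(replicate_peaks):
        for p in rep:
            events.setdefault(p.chrom, []).append((p.start, p.end, r))

    out: List[GenomicInterval] = []
    for chrom in sorted(events):
        rows = sorted(events[chrom])
        comp_start, comp_end = rows[0][0], rows[0][1]
        reps_seen = {rows[0][2]}
        for start, end, r in rows[1:]:
            if start < comp_end:  # strict: >=1 bp overlap with the component
                comp_end = max(comp_end, end)
                reps_seen.add(r)
            else:
                if len(reps_seen) == n_rep:
                    out.append(GenomicInterval(chrom, comp_start, comp_end))
                comp_start, comp_end, reps_seen = start, end, {r}
        if len(reps_seen) == n_rep:
            out.append(GenomicInterval(chrom, comp_start, comp_end))
    return ConsensusPeakSet(dbp, out, n_rep)


def percentile_nearest_rank(values: Sequence[float], pct: float) -> float:
    """Nearest-rank (<=) percentile: smallest value with >= pct% of data at or below it."""
    if not 0 < pct <= 100:
        raise ValueError("percentile must be in (0, 100]")
    ordered = np.sort(np.asarray(values, dtype=float))
    rank = int(np.ceil(pct / 100.0 * len(ordered)))
    return float(ordered[max(rank, 1) - 1])


def filter_by_min_peaks(
    sets: Sequence[ConsensusPeakSet],
    min_peaks: int = 250,
    percentile: Optional[float] = 15,
) -> Tuple[List[ConsensusPeakSet], List[DbpFilterReport]]:
    """Drop DBPs with no reproducible peaks or too few consensus peaks.

    The effective threshold is max(min_peaks, nearest-rank percentile of
    the observed n_peaks distribution).  DBPs meeting the threshold
    (n_peaks >= threshold) are kept.
    """
    if min_peaks < 0:
        raise ValueError("min_peaks must be >= 0")
    threshold = float(min_peaks)
    counts = [s.n_peaks for s in sets]
    if percentile is not None and counts:
        threshold = max(threshold, percentile_nearest_rank(counts, percentile))

    kept: List[ConsensusPeakSet] = []
    reports: List[DbpFilterReport] = []
    for s in sets:
        if s.n_peaks == 0:
            reports.append(DbpFilterReport(s.dbp, 0, False, "no_reproducible_peaks"))
        elif s.n_peaks < threshold:
            reports.append(DbpFilterReport(s.dbp, s.n_peaks, False, "below_min_peaks"))
        else:
            reports.append(DbpFilterReport(s.dbp, s.n_peaks, True, "ok"))
            kept.append(s)
    return kept, reports
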