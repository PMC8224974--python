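"""Per-promoter occupancy summaries: binary matrix, regression, feature annotation.

Binding is scored at the window level: one DBP contributes a single 1 to a
promoter row no matter how many of its consensus peaks fall in the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from promscape.consensus import ConsensusPeakSet
from promscape.genomic_io import GeneModel, GenomicInterval, Peak, PromoterWindow
from promscape.intervals import (
    merge_chrom_arrays,
    overlaps_any,
    to_chrom_arrays,
)

FEATURE_CLASSES = ("promoter_tss", "tts", "exon", "intron", "intergenic")


@dataclass
class OccupancyMatrix:
    """Binary promoters × DBPs matrix; row sums are per-promoter binding-event counts."""

    values: pd.DataFrame  # index = gene ids, columns = dbp names, int8 in {0,1}

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in occupancy matrix")
        bad = ~self.values.isin([0, 1]).all().all()
        if bad:
            raise ValueError("occupancy matrix must be binary")

    @property
    def promoters(self) -> List[str]:
        return list(self.values.index)

    @property
    def dbps(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_dbps(self) -> pd.Series:
        """Per-promoter number of binding events (row sums)."""
        return self.values.sum(axis=1)

    def to_tsv(self, path):
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "OccupancyMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id").astype(np.int8))


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r: float
    p: float
    n: int

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("regression requires n >= 3")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def count_feature_overlaps(
    cset: ConsensusPeakSet, features: Sequence
) -> int:
    """Number of FEATURES overlapped (>=1 bp) by at least one consensus peak.

    Features may overlap each other; each is tested independently against
    the merged peak set.
    """
    peaks = merge_chrom_arrays(to_chrom_arrays(cset.intervals))
    total = 0
    feats = to_chrom_arrays(features)
    for chrom, (fs, fe) in feats.items():
        if chrom not in peaks:
            continue
        ps, pe = peaks[chrom]
        total += int(overlaps_any(fs, fe, ps, pe).sum())
    return total


def build_occupancy_matrix(
    sets: Sequence[ConsensusPeakSet], promoters: Sequence[PromoterWindow]
) -> OccupancyMatrix:
    """Binary matrix: entry (gene, dbp) = 1 iff >=1 bp peak/window overlap."""
    gene_ids = [w.gene_id for w in promoters]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids among promoter windows")
    # per-chromosome promoter arrays with original positions
    by_chrom: Dict[str, List[Tuple[int, int, int]]] = {}
    for i, w in enumerate(promoters):
        by_chrom.setdefault(w.chrom, []).append((w.start, w.end, i))
    mat = np.zeros((len(promoters), len(sets)), dtype=np.int8)
    for j, cset in enumerate(sets):
        peaks = merge_chrom_arrays(to_chrom_arrays(cset.intervals))
        for chrom, rows in by_chrom.items():
            if chrom not in peaks:
                continue
            arr = np.asarray(rows, dtype=np.int64)
            ps, pe = peaks[chrom]
            hit = overlaps_any(arr[:, 0], arr[:, 1], ps, pe)
            mat[arr[hit, 2], j] = 1
    df = pd.DataFrame(mat, index=gene_ids, columns=[s.dbp for s in sets])
    return OccupancyMatrix(df)


def fit_peaknum_regression(
    points: Sequence[Tuple[float, float]]
) -> RegressionFit:
    """OLS of n_overlapping_features on n_peaks with Pearson r and two-sided p."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need >= 3 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=len(pts),
    )


def annotate_peak_features(
    peaks: Sequence,
    genes: Sequence[GeneModel],
    promoter_flank: int = 3000,
    tts_flank: int = 1000,
) -> pd.DataFrame:
    """Assign each peak one genomic-feature class by midpoint position.

    Precedence: promoter/TSS > TTS > exon > intron > intergenic.  Returns
    per-DBP fractions (rows sum to 1).  Accepts Peaks or, for a single
    anonymous set, plain GenomicIntervals (grouped under dbp '.').
    """
    raw: Dict[str, Dict[str, List[Tuple[int, int]]]] = {
        "promoter_tss": {}, "tts": {}, "exon": {}, "intron": {},
    }
    for g in genes:
        t = g.tss
        tts_pos = g.span.end - 1 if g.strand == "+" else g.span.start
        raw["promoter_tss"].setdefault(g.chrom, []).append(
            (max(0, t - promoter_flank), t + promoter_flank)
        )
        raw["tts"].setdefault(g.chrom, []).append(
            (max(0, tts_pos - tts_flank), tts_pos + tts_flank)
        )
        raw["intron"].setdefault(g.chrom, []).append((g.span.start, g.span.end))
        for e in g.exons:
            raw["exon"].setdefault(g.chrom, []).append((e.start, e.end))
    merged = {
        cls: {
            c: _merge_pairs(pairs) for c, pairs in table.items()
        }
        for cls, table in raw.items()
    }

    def _contains(cls: str, chrom: str, pos: int) -> bool:
        tab = merged[cls].get(chrom)
        if tab is None:
            return False
        ms, me = tab
        i = np.searchsorted(ms, pos, side="right") - 1
        return i >= 0 and me[i] > pos

    counts: Dict[str, Dict[str, int]] = {}
    for p in peaks:
        if isinstance(p, Peak):
            dbp, iv = p.dbp, p.interval
        else:
            dbp, iv = ".", p
        mid = (iv.start + iv.end) // 2
        for cls in ("promoter_tss", "tts", "exon", "intron"):
            if _contains(cls, iv.chrom, mid):
                break
        else:
            cls = "intergenic"
        counts.setdefault(dbp, {c: 0 for c in FEATURE_CLASSES})[cls] += 1

    rows = {}
    for dbp, c in counts.items():
        total = sum(c.values())
        rows[dbp] = {k: c[k] / total for k in FEATURE_CLASSES}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_CLASSES))


def cluster_binary_profiles(
    matrix: OccupancyMatrix,
    over: str = "dbps",
    metric: str = "euclidean",
    method: str = "complete",
    cut_height: Optional[float] = None,
):
    """Hierarchical clustering of binary binding vectors.

    Returns (linkage matrix, labels, metadata).  Labels are flat cluster
    ids at ``cut_height`` (or each item's own cluster when None), relabelled
    by first appearance so output is deterministic.
    """
    if over not in ("dbps", "promoters"):
        raise ValueError("over must be 'dbps' or 'promoters'")
    data = matrix.values.T if over == "dbps" else matrix.values
    if len(data) < 2:
        raise ValueError("need >= 2 items to cluster")
    dist = pdist(data.to_numpy(dtype=float), metric=metric)
    Z = linkage(dist, method=method)
    if cut_height is None:
        labels = np.arange(1, len(data) + 1)
    else:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    labels = _relabel_by_first_appearance(labels)
    meta = {"metric": metric, "method": method, "cut_height": cut_height}
    return Z, pd.Series(labels, index=data.index, name="cluster"), meta


def _merge_pairs(pairs: List[Tuple[int, int]]) -> Tuple[np.ndarray, np.ndarray]:
    from promscape.intervals import merge_arrays

    arr = np.asarray(sorted(pairs), dtype=np.int64)
    return merge_arrays(arr[:, 0], arr[:, 1])


def _relabel_by_first_appearance(labels: np.ndarray) -> np.ndarray:
    mapping: Dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out
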