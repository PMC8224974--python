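"""Reservoir promoter classification and its companion analyses.

A *reservoir* is a promoter with strictly more than ``min_dbps`` binding
events (default 7) yet total RNA-seq TPM strictly below ``tpm_off``
(default 0.001).  Reservoirs split into *ghosts* (nascent PRO-seq window
TPM below the ghost threshold) and *zombies* (detectable nascent but no
mature RNA).  The *conservative* subset additionally lacks expression in
every total/polyA RNA sample quantified over the promoter window itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from promscape.genomic_io import GeneModel, GenomicInterval, PromoterWindow
from promscape.intervals import merge_chrom_arrays, overlaps_any, to_chrom_arrays
from promscape.occupancy import OccupancyMatrix

log = logging.getLogger(__name__)

NEIGHBOR_CLASSES = ("multiple_nearby", "bidirectional", "same_strand_nearby", "none")


def find_count_threshold(
    n_dbps: Sequence[float],
    mode: str = "fixed",
    fixed: int = 7,
    smooth_sigma: float = 1.5,
) -> int:
    """Binding-event threshold separating the two modes of the n_dbps distribution.

    ``mode='fixed'`` returns the configured threshold (default 7, the
    valley of the observed bimodal distribution).  ``mode='valley'``
    smooths the integer histogram with a Gaussian kernel and returns the
    deepest minimum between the two largest local maxima; if the smoothed
    histogram is unimodal it warns and falls back to ``fixed``.
    """
    values = np.asarray(list(n_dbps))
    if len(values) == 0:
        raise ValueError("empty n_dbps distribution")
    if mode == "fixed":
        return int(fixed)
    if mode != "valley":
        raise ValueError("mode must be 'fixed' or 'valley'")
    hist = np.bincount(values.astype(int))
    smooth = gaussian_filter1d(hist.astype(float), smooth_sigma)
    peaks = [
        i
        for i in range(1, len(smooth) - 1)
        if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]
    ]
    if len(peaks) < 2:
        log.warning("n_dbps distribution unimodal; falling back to fixed threshold")
        return int(fixed)
    top2 = sorted(sorted(peaks, key=lambda i: smooth[i], reverse=True)[:2])
    lo, hi = top2
    valley = lo + int(np.argmin(smooth[lo : hi + 1]))
    return int(valley)


def call_reservoirs(
    matrix: OccupancyMatrix,
    tpm_total: Mapping[str, float],
    biotypes: Optional[Mapping[str, str]] = None,
    min_dbps: int = 7,
    tpm_off: float = 0.001,
) -> pd.DataFrame:
    """Per-promoter reservoir calls.

    is_reservoir = (n_dbps > min_dbps) AND (tpm_total < tpm_off), both
    strict.  Returns a calls table indexed by gene id with columns
    n_dbps, tpm_total, biotype, is_reservoir, subclass (initially 'none'),
    and placeholders for downstream annotations.
    """
    tpm = pd.Series(tpm_total).reindex(matrix.promoters)
    if tpm.isna().any():
        missing = list(tpm.index[tpm.isna()])[:5]
        raise ValueError(f"expression missing for promoters, e.g. {missing}")
    calls = pd.DataFrame(index=pd.Index(matrix.promoters, name="gene_id"))
    calls["n_dbps"] = matrix.n_dbps
    calls["tpm_total"] = tpm
    if biotypes is not None:
        calls["biotype"] = pd.Series(biotypes).reindex(calls.index)
    calls["is_reservoir"] = (calls["n_dbps"] > min_dbps) & (calls["tpm_total"] < tpm_off)
    calls["subclass"] = "none"
    calls["neighbor_class"] = "none"
    calls["se_overlap"] = False
    calls["conservative"] = False
    calls["polII_bound"] = False
    return calls


def flag_superenhancer_overlap(
    calls: pd.DataFrame,
    promoters: Sequence[PromoterWindow],
    se_intervals: Sequence[GenomicInterval],
) -> Tuple[pd.DataFrame, int]:
    """Flag promoters whose window overlaps >=1 super-enhancer interval.

    Returns the updated calls and the number of flagged *reservoirs*.
    """
    merged = merge_chrom_arrays(to_chrom_arrays(se_intervals))
    flags = {}
    for w in promoters:
        tab = merged.get(w.chrom)
        if tab is None:
            flags[w.gene_id] = False
            continue
        hit = overlaps_any(
            np.array([w.start]), np.array([w.end]), tab[0], tab[1]
        )
        flags[w.gene_id] = bool(hit[0])
    calls = calls.copy()
    calls["se_overlap"] = pd.Series(flags).reindex(calls.index).fillna(False)
    n_res_overlap = int((calls["se_overlap"] & calls["is_reservoir"]).sum())
    return calls, n_res_overlap


def _neighbor_class_one(
    q_tss: int,
    q_strand: str,
    neighbors: Sequence[Tuple[int, str]],
    distance: int,
) -> str:
    """Classify one promoter given (tss, strand) of all OTHER same-chromosome genes.

    Precedence: multiple_nearby (>=2 other TSSs within `distance`, any
    strand) > bidirectional (>=1 opposite-strand TSS strictly upstream
    within `distance`) > same_strand_nearby (same-strand upstream) > none.
    "Upstream" is measured against the QUERY's orientation; distances are
    TSS-to-TSS with strict <= and a TSS at offset 0 not counted as upstream.
    """
    within = [(t, s) for t, s in neighbors if abs(t - q_tss) <= distance]
    if len(within) >= 2:
        return "multiple_nearby"

    def upstream(t: int) -> bool:
        d = q_tss - t if q_strand == "+" else t - q_tss
        return 0 < d <= distance

    if any(s != q_strand and upstream(t) for t, s in within):
        return "bidirectional"
    if any(s == q_strand and upstream(t) for t, s in within):
        return "same_strand_nearby"
    return "none"


def classify_neighbors(
    genes: Sequence[GeneModel], distance: int = 1000
) -> pd.Series:
    """Neighbor class for every gene (see _neighbor_class_one for the rules)."""
    by_chrom: Dict[str, List[Tuple[int, str, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.strand, g.gene_id))
    out = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        tss = np.array([r[0] for r in rows])
        for i, (t, s, gid) in enumerate(rows):
            lo = np.searchsorted(tss, t - distance, side="left")
            hi = np.searchsorted(tss, t + distance, side="right")
            neigh = [
                (rows[k][0], rows[k][1]) for k in range(lo, hi) if k != i
            ]
            out[gid] = _neighbor_class_one(t, s, neigh, distance)
    return pd.Series(out, name="neighbor_class")


def classify_neighbor(
    genes: Sequence[GeneModel], query_gene_id: str, distance: int = 1000
) -> str:
    """Neighbor class of a single gene within the full annotation."""
    query = next((g for g in genes if g.gene_id == query_gene_id), None)
    if query is None:
        raise KeyError(f"gene {query_gene_id!r} absent from annotation")
    neighbors = [
        (g.tss, g.strand)
        for g in genes
        if g.gene_id != query_gene_id and g.chrom == query.chrom
    ]
    return _neighbor_class_one(query.tss, query.strand, neighbors, distance)


def neighbor_expression_status(
    calls: pd.DataFrame,
    genes: Sequence[GeneModel],
    tpm: Mapping[str, float],
    distance: int = 1000,
    tpm_off: float = 0.001,
) -> Tuple[float, float, float, pd.Series]:
    """Among promoters with >=1 neighbor within `distance`: is any neighbor expressed?

    Returns (fraction of reservoirs-with-neighbors that have an expressed
    neighbor, chi-squared statistic, p) for the 2x2 reservoir-vs-not x
    expressed-neighbor-vs-not table, plus the per-gene boolean series
    (NaN for genes without neighbors).
    """
    tpm_s = pd.Series(tpm)
    by_chrom: Dict[str, List[Tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    status: Dict[str, object] = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        tss = np.array([r[0] for r in rows])
        for i, (t, gid) in enumerate(rows):
            lo = np.searchsorted(tss, t - distance, side="left")
            hi = np.searchsorted(tss, t + distance, side="right")
            neigh = [rows[k][1] for k in range(lo, hi) if k != i]
            if not neigh:
                status[gid] = np.nan
            else:
                status[gid] = bool((tpm_s.reindex(neigh) >= tpm_off).any())
    series = pd.Series(status).reindex(calls.index)
    has_neigh = series.notna()
    expressed = series[has_neigh].astype(bool)
    is_res = calls.loc[has_neigh.index[has_neigh], "is_reservoir"].astype(bool)
    res_with = expressed[is_res]
    fraction = float(res_with.mean()) if len(res_with) else float("nan")
    table = [
        [int((expressed & is_res).sum()), int((~expressed & is_res).sum())],
        [int((expressed & ~is_res).sum()), int((~expressed & ~is_res).sum())],
    ]
    if min(sum(r) for r in table) == 0 or min(sum(c) for c in zip(*table)) == 0:
        chi2, p = float("nan"), float("nan")
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return fraction, float(chi2), float(p), series


def window_neighborhood_expression(
    genes: Sequence[GeneModel],
    tpm: Mapping[str, float],
    calls: pd.DataFrame,
    k: int = 5,
    exclude_se_reservoirs: bool = True,
) -> Tuple[pd.DataFrame, Dict[str, Tuple[float, float]]]:
    """Mean TPM of the k-1 genes flanking each center gene (center excluded).

    Genes are ordered by TSS within each chromosome; only full windows
    ((k-1)/2 genes each side) contribute.  Two-sided Wilcoxon rank-sum
    tests compare reservoir-centred vs non-reservoir-centred windows
    (SE-overlapping reservoirs excluded from the reservoir group when
    requested) and SE-centred vs non-SE-centred windows.
    """
    if k < 3 or k % 2 == 0:
        raise ValueError("k must be an odd integer >= 3")
    half = (k - 1) // 2
    tpm_s = pd.Series(tpm)
    by_chrom: Dict[str, List[Tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    records = []
    for chrom, rows in by_chrom.items():
        rows.sort()
        ids = [r[1] for r in rows]
        if len(ids) < k:
            continue
        vals = tpm_s.reindex(ids).to_numpy(dtype=float)
        for i in range(half, len(ids) - half):
            neigh = np.concatenate([vals[i - half : i], vals[i + 1 : i + half + 1]])
            records.append((ids[i], float(neigh.mean())))
    df = pd.DataFrame(records, columns=["gene_id", "neighbor_mean_tpm"]).set_index(
        "gene_id"
    )
    joined = df.join(calls[["is_reservoir", "se_overlap"]], how="inner")

    res_mask = joined["is_reservoir"].astype(bool)
    if exclude_se_reservoirs:
        res_mask &= ~joined["se_overlap"].astype(bool)
    tests: Dict[str, Tuple[float, float]] = {}
    a = joined.loc[res_mask, "neighbor_mean_tpm"]
    b = joined.loc[~joined["is_reservoir"].astype(bool), "neighbor_mean_tpm"]
    if len(a) and len(b):
        s, p = stats.ranksums(a, b)
        tests["reservoir_vs_non"] = (float(s), float(p))
    se_mask = joined["se_overlap"].astype(bool)
    if se_mask.any() and (~se_mask).any():
        s, p = stats.ranksums(
            joined.loc[se_mask, "neighbor_mean_tpm"],
            joined.loc[~se_mask, "neighbor_mean_tpm"],
        )
        tests["se_vs_non"] = (float(s), float(p))
    return joined, tests


def classify_ghost_zombie(
    calls: pd.DataFrame,
    proseq_window_tpm: Mapping[str, float],
    ghost_tpm: float = 0.001,
) -> pd.DataFrame:
    """Split reservoirs into ghosts (nascent TPM < ghost_tpm) and zombies."""
    pro = pd.Series(proseq_window_tpm).reindex(calls.index)
    res = calls["is_reservoir"].astype(bool)
    if pro[res].isna().any():
        raise ValueError("PRO-seq window TPM missing for some reservoirs")
    calls = calls.copy()
    calls["tpm_proseq_window"] = pro
    calls["subclass"] = "none"
    calls.loc[res & (pro < ghost_tpm), "subclass"] = "ghost"
    calls.loc[res & (pro >= ghost_tpm), "subclass"] = "zombie"
    return calls


def conservative_set(
    calls: pd.DataFrame,
    window_tpm: pd.DataFrame,
    tpm_off: float = 0.001,
) -> pd.DataFrame:
    """Reservoirs with window TPM < tpm_off in EVERY total/polyA RNA sample."""
    if window_tpm.shape[1] == 0:
        raise ValueError("window_tpm must contain at least one sample column")
    wt = window_tpm.reindex(calls.index)
    all_silent = (wt < tpm_off).all(axis=1) & wt.notna().all(axis=1)
    calls = calls.copy()
    calls["conservative"] = calls["is_reservoir"].astype(bool) & all_silent
    return calls


def flag_polii_bound(
    calls: pd.DataFrame, matrix: OccupancyMatrix, polii_dbps: Iterable[str]
) -> pd.DataFrame:
    """polII_bound = occupancy by any DBP in the configured Pol II machinery list."""
    names = [d for d in polii_dbps if d in matrix.values.columns]
    calls = calls.copy()
    if names:
        calls["polII_bound"] = (
            matrix.values[names].sum(axis=1).reindex(calls.index) > 0
        )
    else:
        calls["polII_bound"] = False
    return calls


def chromatin_association(
    mark_flags: Mapping[str, bool],
    proseq_tpm: Mapping[str, float],
    subset: Optional[Sequence[str]] = None,
) -> Dict[str, float]:
    """Mean nascent TPM with vs without a chromatin mark, ratio and rank-sum p.

    ``subset`` restricts the comparison (e.g. to reservoirs).  An empty
    group yields NaNs with a warning.
    """
    flags = pd.Series(mark_flags).astype(bool)
    tpm = pd.Series(proseq_tpm)
    idx = flags.index.intersection(tpm.index)
    if subset is not None:
        idx = idx.intersection(pd.Index(subset))
    flags, tpm = flags.reindex(idx), tpm.reindex(idx)
    with_mark = tpm[flags]
    without = tpm[~flags]
    if len(with_mark) == 0 or len(without) == 0:
        log.warning("chromatin_association: one group empty; returning NaNs")
        return dict(
            mean_with=float("nan"), mean_without=float("nan"),
            ratio=float("nan"), p=float("nan"),
            n_with=len(with_mark), n_without=len(without),
        )
    mw, mo = float(with_mark.mean()), float(without.mean())
    s, p = stats.ranksums(with_mark, without)
    return dict(
        mean_with=mw,
        mean_without=mo,
        ratio=mw / mo if mo > 0 else float("inf"),
        p=float(p),
        n_with=len(with_mark),
        n_without=len(without),
    )
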