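"""TPM quantification, expression bins, and binding-expression correlation.

TPM: rate_i = count_i / effective_length_i; TPM_i = 1e6 * rate_i / sum(rates).
Every sample column therefore sums to exactly 1e6 whenever it has any
counts.  Window quantification is multi-overlap: a read increments EVERY
window it overlaps by >=1 bp (windows may overlap each other).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from promscape.genomic_io import GenomicInterval, PromoterWindow

#: Expression-bin edges in TPM: off < 0.001 <= low <= 0.137 < medium <= 3 < high
DEFAULT_BIN_EDGES = (0.001, 0.137, 3.0)

ASSAYS = ("total_rna", "polya_rna", "pro_seq")


@dataclass
class CountsTable:
    """Feature x sample integer counts with per-feature effective lengths."""

    counts: pd.DataFrame  # features x samples, non-negative ints
    lengths: pd.Series  # feature -> effective length (bp)
    assays: Dict[str, str] = field(default_factory=dict)  # sample -> assay tag

    def __post_init__(self):
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("effective length missing for some features")
        if (self.lengths <= 0).any():
            raise ValueError("effective lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class ExpressionMatrix:
    """Feature x sample TPM values with per-sample assay tags."""

    tpm: pd.DataFrame
    assays: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for s, a in self.assays.items():
            if a not in ASSAYS:
                raise ValueError(f"unknown assay tag {a!r} for sample {s!r}")

    def samples_for(self, assay: str) -> list:
        return [s for s, a in self.assays.items() if a == assay and s in self.tpm.columns]

    def mean_by_assay(self) -> pd.DataFrame:
        """Average TPM across replicate samples of each assay."""
        out = {}
        for assay in ASSAYS:
            cols = self.samples_for(assay)
            if cols:
                out[assay] = self.tpm[cols].mean(axis=1)
        return pd.DataFrame(out)


def tpm_from_counts(table: CountsTable) -> ExpressionMatrix:
    """Length-normalised TPM; errors on an all-zero sample."""
    rates = table.counts.div(table.lengths, axis=0)
    sums = rates.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero samples: {list(zero.index)}")
    tpm = rates.div(sums, axis=1) * 1e6
    return ExpressionMatrix(tpm, dict(table.assays))


def quantify_window(
    reads: Mapping[str, Sequence[GenomicInterval]],
    windows: Sequence[PromoterWindow],
    assays: Optional[Mapping[str, str]] = None,
) -> CountsTable:
    """Multi-overlap counting of read intervals into promoter windows.

    A read increments every window it overlaps by >=1 bp.  The window
    width is used as the effective length for downstream TPM.
    """
    ids = [w.gene_id for w in windows]
    by_chrom: Dict[str, list] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append((w.start, w.end, i))
    chrom_arrays = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        arr = np.asarray(rows, dtype=np.int64)
        max_w = int((arr[:, 1] - arr[:, 0]).max())
        chrom_arrays[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2], max_w)

    counts = np.zeros((len(windows), len(reads)), dtype=np.int64)
    for j, (sample, intervals) in enumerate(reads.items()):
        for iv in intervals:
            tab = chrom_arrays.get(iv.chrom)
            if tab is None:
                continue
            ws, we, idx, max_w = tab
            lo = np.searchsorted(ws, iv.start - max_w, side="left")
            hi = np.searchsorted(ws, iv.end, side="left")
            for k in range(lo, hi):
                if we[k] > iv.start and ws[k] < iv.end:
                    counts[idx[k], j] += 1
    df = pd.DataFrame(counts, index=ids, columns=list(reads))
    lengths = pd.Series({w.gene_id: w.interval.width for w in windows})
    return CountsTable(df, lengths, dict(assays or {}))


def classify_expression_bin(
    tpm: float, edges: Tuple[float, float, float] = DEFAULT_BIN_EDGES
) -> str:
    """Bin a TPM value: off < e0; low in [e0, e1]; medium in (e1, e2]; high > e2.

    The first boundary follows the printed rule "off: < e0", so a value
    exactly at e0 falls in 'low' (right-closed upper bounds elsewhere).
    """
    if tpm < 0:
        raise ValueError("TPM must be non-negative")
    e0, e1, e2 = edges
    if not (0 < e0 < e1 < e2):
        raise ValueError("bin edges must be strictly increasing and positive")
    if tpm < e0:
        return "off"
    if tpm <= e1:
        return "low"
    if tpm <= e2:
        return "medium"
    return "high"


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


def binding_expression_correlation(
    n_dbps: Sequence[float],
    tpm: Sequence[float],
    pseudocount: float = 0.001,
) -> CorrelationResult:
    """Pearson (on log10(TPM + pseudocount)) and Spearman correlation.

    The pseudocount defaults to the 'off' threshold so that silent
    promoters land at log10(0.001) rather than -inf.
    """
    x = np.asarray(n_dbps, dtype=float)
    y = np.asarray(tpm, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    logy = np.log10(y + pseudocount)
    if np.ptp(x) == 0 or np.ptp(logy) == 0:
        raise ValueError("zero variance in binding counts or expression")
    pr, pp = stats.pearsonr(x, logy)
    sr, sp = stats.spearmanr(x, y)
    return CorrelationResult(float(pr), float(pp), float(sr), float(sp), len(x))
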