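"""Constrained-shuffle permutation enrichment plus the categorical tests.

The null preserves, per chromosome, (i) the number of peaks, (ii) the
multiset of peak widths and (iii) peak-to-chromosome assignment; each
shuffled start is uniform on [0, L - w].  Shuffled peaks may overlap each
other (no rejection).  The default overlap statistic is the number of
PEAKS overlapping >=1 feature, which makes the Fisher 2x2 rows sum to the
peak count; the feature-unit statistic is also available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from promscape._rng import substream
from promscape.consensus import ConsensusPeakSet
from promscape.genomic_io import GenomeAssembly, GenomicInterval, RepeatElement
from promscape.intervals import (
    merge_chrom_arrays,
    overlaps_any,
    to_chrom_arrays,
)
from promscape.occupancy import OccupancyMatrix


@dataclass
class PermutationNull:
    """Observed overlap vs an empirical shuffle null for one DBP x feature set."""

    dbp: str
    feature_set: str
    observed: int
    null_draws: np.ndarray
    null_mean: float
    null_sd: float
    z: Optional[float]
    p_empirical: float
    p_fisher: Optional[float]
    direction: str  # enriched | depleted | ns | undefined
    n_peaks: int

    def __post_init__(self):
        if not 0 <= self.p_empirical <= 1:
            raise ValueError("p_empirical outside [0, 1]")
        if (self.z is None) != (self.null_sd == 0):
            raise ValueError("z undefined iff null sd is zero")


@dataclass(frozen=True)
class BiasTestResult:
    """2x2 bound/unbound x biotype test for one DBP."""

    dbp: str
    log2_obs_exp: float
    statistic: float
    p: float
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    valid: bool = True


def shuffle_peaks(
    cset: ConsensusPeakSet, genome: GenomeAssembly, seed: int
) -> List[GenomicInterval]:
    """One constrained shuffle of a consensus peak set (see module docstring)."""
    rng = substream(seed, "shuffle", cset.dbp)
    out: List[GenomicInterval] = []
    arrays = to_chrom_arrays(cset.intervals)
    for chrom in sorted(arrays):
        starts, ends = arrays[chrom]
        widths = ends - starts
        L = genome.length(chrom)
        if (widths > L).any():
            raise ValueError(f"peak wider than chromosome {chrom}")
        new_starts = rng.integers(0, L - widths + 1)
        for s, w in zip(new_starts, widths):
            out.append(GenomicInterval(chrom, int(s), int(s + w)))
    return out


def _count_peaks_overlapping(
    peak_arrays, merged_features
) -> int:
    total = 0
    for chrom, (ps, pe) in peak_arrays.items():
        feats = merged_features.get(chrom)
        if feats is None:
            continue
        total += int(overlaps_any(ps, pe, feats[0], feats[1]).sum())
    return total


def _count_features_overlapped(feature_arrays, peak_arrays) -> int:
    merged = merge_chrom_arrays(peak_arrays)
    total = 0
    for chrom, (fs, fe) in feature_arrays.items():
        peaks = merged.get(chrom)
        if peaks is None:
            continue
        total += int(overlaps_any(fs, fe, peaks[0], peaks[1]).sum())
    return total


def empirical_p_two_sided(null_draws: np.ndarray, observed: float) -> float:
    """Two-sided add-one empirical p on the absolute deviation from the null mean.

    Counts null draws at least as far from the null mean as the
    observation (either side), with the observation itself added as one
    extra draw, so the p-value is never 0:

        p = (1 + #{ |draw - mean| >= |obs - mean| }) / (n_perm + 1)

    On discrete overlap counts this single-tail form of the centred
    statistic stays close to uniform under the null, where doubling
    min(upper, lower) tails is markedly conservative.
    """
    n = len(null_draws)
    centered = np.abs(null_draws - null_draws.mean())
    extreme = int((centered >= abs(observed - null_draws.mean())).sum())
    return (1 + extreme) / (n + 1)


def permutation_enrichment(
    cset: ConsensusPeakSet,
    features: Sequence,
    genome: GenomeAssembly,
    n_perm: int = 1000,
    seed: int = 0,
    feature_set: str = "features",
    unit: str = "peaks",
    alpha: float = 0.05,
) -> PermutationNull:
    """Observed overlap vs the constrained-shuffle null for one DBP x feature set.

    ``unit='peaks'`` (default) counts peaks overlapping >=1 feature;
    ``unit='features'`` counts features overlapped by >=1 peak.  Each
    (dbp, feature_set) pair draws from its own named substream of ``seed``,
    so results are independent of execution order.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if unit not in ("peaks", "features"):
        raise ValueError("unit must be 'peaks' or 'features'")
    peak_arrays = to_chrom_arrays(cset.intervals)
    feature_arrays = to_chrom_arrays(features)
    merged_features = merge_chrom_arrays(feature_arrays)
    n_peaks = cset.n_peaks

    if unit == "peaks":
        observed = _count_peaks_overlapping(peak_arrays, merged_features)
    else:
        observed = _count_features_overlapped(feature_arrays, peak_arrays)

    rng = substream(seed, "perm", cset.dbp, feature_set)
    draws = np.zeros(n_perm, dtype=np.int64)
    for chrom in sorted(peak_arrays):
        starts, ends = peak_arrays[chrom]
        widths = ends - starts
        L = genome.length(chrom)
        if (widths > L).any():
            raise ValueError(f"peak wider than chromosome {chrom}")
        # n_perm x n_peaks matrix of shuffled starts for this chromosome
        new_starts = rng.integers(0, L - widths + 1, size=(n_perm, len(widths)))
        new_ends = new_starts + widths
        if unit == "peaks":
            feats = merged_features.get(chrom)
            if feats is None:
                continue
            ts, te = feats
            idx = np.searchsorted(ts, new_ends.ravel(), side="left") - 1
            hit = idx >= 0
            hit[hit] = te[idx[hit]] > new_starts.ravel()[hit]
            draws += hit.reshape(n_perm, -1).sum(axis=1)
        else:
            feats = feature_arrays.get(chrom)
            if feats is None:
                continue
            from promscape.intervals import merge_arrays

            fs, fe = feats
            for i in range(n_perm):
                ms, me = merge_arrays(new_starts[i], new_ends[i])
                draws[i] += int(overlaps_any(fs, fe, ms, me).sum())

    null_mean = float(draws.mean())
    null_sd = float(draws.std(ddof=1)) if n_perm > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else None
    p_emp = empirical_p_two_sided(draws, observed)

    p_fisher = None
    if unit == "peaks" and n_peaks > 0:
        expected = int(round(null_mean))
        table = [
            [observed, n_peaks - observed],
            [expected, n_peaks - expected],
        ]
        p_fisher = float(stats.fisher_exact(table, alternative="two-sided")[1])

    if null_sd == 0:
        direction = "undefined"
    elif p_emp < alpha:
        direction = "enriched" if observed > null_mean else "depleted"
    else:
        direction = "ns"

    return PermutationNull(
        dbp=cset.dbp,
        feature_set=feature_set,
        observed=observed,
        null_draws=draws,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p_empirical=p_emp,
        p_fisher=p_fisher,
        direction=direction,
        n_peaks=n_peaks,
    )


def repeat_enrichment_matrix(
    sets: Sequence[ConsensusPeakSet],
    repeats: Sequence[RepeatElement],
    genome: GenomeAssembly,
    by: str = "family",
    n_perm: int = 1000,
    seed: int = 0,
    groups: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[Tuple[str, str], PermutationNull]]:
    """Z and empirical-p matrices (DBP x repeat group) under the shuffle null.

    ``by`` selects grouping by 'family' or 'class'.  Requesting a group
    absent from the annotation is an error.
    """
    if by not in ("family", "class"):
        raise ValueError("by must be 'family' or 'class'")
    key = (lambda r: r.family) if by == "family" else (lambda r: r.repeat_class)
    grouped: Dict[str, List[RepeatElement]] = {}
    for r in repeats:
        grouped.setdefault(key(r), []).append(r)
    if groups is None:
        groups = sorted(grouped)
    else:
        missing = [g for g in groups if g not in grouped]
        if missing:
            raise ValueError(f"repeat groups absent from annotation: {missing}")

    z = pd.DataFrame(index=[s.dbp for s in sets], columns=list(groups), dtype=float)
    p = pd.DataFrame(index=[s.dbp for s in sets], columns=list(groups), dtype=float)
    nulls: Dict[Tuple[str, str], PermutationNull] = {}
    for cset in sets:
        for g in groups:
            res = permutation_enrichment(
                cset,
                [r.interval for r in grouped[g]],
                genome,
                n_perm=n_perm,
                seed=seed,
                feature_set=f"{by}:{g}",
            )
            nulls[(cset.dbp, g)] = res
            z.loc[cset.dbp, g] = np.nan if res.z is None else res.z
            p.loc[cset.dbp, g] = res.p_empirical
    return z, p, nulls


def biotype_bias_test(
    matrix: OccupancyMatrix, biotypes: Mapping[str, str]
) -> List[BiasTestResult]:
    """Per-DBP 2x2 chi-squared test of lncRNA vs mRNA promoter binding bias.

    Table rows are bound/unbound, columns lncRNA/mRNA.  The log2
    observed/expected ratio is computed on the bound-lncRNA cell; DBPs
    bound to zero promoters are flagged invalid.  The statistic is the
    textbook (uncorrected) sum of (O-E)^2/E.
    """
    bt = pd.Series(biotypes).reindex(matrix.promoters)
    if bt.isna().any():
        raise ValueError("biotype missing for some promoters")
    is_lnc = (bt == "lncRNA").to_numpy()
    is_m = (bt == "mRNA").to_numpy()
    if not is_lnc.any() or not is_m.any():
        raise ValueError("both biotypes must be present")
    results = []
    vals = matrix.values.to_numpy()
    n_lnc, n_m = int(is_lnc.sum()), int(is_m.sum())
    for j, dbp in enumerate(matrix.dbps):
        bound = vals[:, j].astype(bool)
        bl = int((bound & is_lnc).sum())
        bm = int((bound & is_m).sum())
        table = ((bl, bm), (n_lnc - bl, n_m - bm))
        if bl + bm == 0:
            results.append(BiasTestResult(dbp, np.nan, np.nan, np.nan, table, False))
            continue
        chi2, pval, _, expected = stats.chi2_contingency(table, correction=False)
        exp_bl = expected[0][0]
        log2oe = float(np.log2(bl / exp_bl)) if bl > 0 and exp_bl > 0 else -np.inf
        results.append(BiasTestResult(dbp, log2oe, float(chi2), float(pval), table))
    return results


def hypergeometric_overrepresentation(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) <= N) or n > N or K > N:
        raise ValueError("hypergeometric bounds violated")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def reservoir_dbp_bias(
    matrix: OccupancyMatrix,
    reservoir_flags: Mapping[str, bool],
    p_threshold: float = 0.001,
    fold: float = 2.0,
) -> Tuple[List[str], List[str], pd.DataFrame]:
    """DBPs enriched/depleted on reservoir promoters (chi-squared + fold filter).

    The fold change is the ratio of bound fractions (reservoir vs
    non-reservoir); a DBP is reported only if p < p_threshold AND the
    fold change exceeds ``fold`` in either direction.
    """
    flags = pd.Series(reservoir_flags).reindex(matrix.promoters).astype(bool)
    res = flags.to_numpy()
    if not res.any() or res.all():
        raise ValueError("both reservoir and non-reservoir promoters required")
    n_res, n_non = int(res.sum()), int((~res).sum())
    rows = []
    vals = matrix.values.to_numpy()
    for j, dbp in enumerate(matrix.dbps):
        bound = vals[:, j].astype(bool)
        br = int((bound & res).sum())
        bn = int((bound & ~res).sum())
        table = [[br, bn], [n_res - br, n_non - bn]]
        frac_r = br / n_res
        frac_n = bn / n_non
        if br + bn == 0:
            rows.append((dbp, np.nan, np.nan, frac_r, frac_n, "na"))
            continue
        chi2, pval, _, _ = stats.chi2_contingency(table, correction=False)
        if frac_n == 0:
            fc = np.inf if frac_r > 0 else np.nan
        else:
            fc = frac_r / frac_n
        call = "ns"
        if pval < p_threshold and fc > fold:
            call = "enriched"
        elif pval < p_threshold and fc < 1.0 / fold:
            call = "depleted"
        rows.append((dbp, float(chi2), float(pval), frac_r, frac_n, call))
    df = pd.DataFrame(
        rows,
        columns=["dbp", "chi2", "p", "frac_reservoir", "frac_nonreservoir", "call"],
    ).set_index("dbp")
    enriched = list(df.index[df["call"] == "enriched"])
    depleted = list(df.index[df["call"] == "depleted"])
    return enriched, depleted, df


def nulls_to_frame(nulls: Sequence[PermutationNull]) -> pd.DataFrame:
    """Serialize PermutationNull records to the standard enrichment table."""
    rows = [
        dict(
            dbp=r.dbp,
            feature_set=r.feature_set,
            observed=r.observed,
            null_mean=r.null_mean,
            null_sd=r.null_sd,
            z=np.nan if r.z is None else r.z,
            p_empirical=r.p_empirical,
            p_fisher=np.nan if r.p_fisher is None else r.p_fisher,
            direction=r.direction,
        )
        for r in nulls
    ]
    return pd.DataFrame(rows)
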