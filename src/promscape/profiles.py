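"""Anchor-centred coverage metaprofiles and profile-shape clustering.

Coverage tracks use bedGraph semantics (stepwise values, absent = 0).  TSS
profiles are strand-aware: minus-strand windows are reversed before
averaging so "downstream" always means transcription-downstream.  Element
profiles rescale each element body to a fixed number of bins (exact
fractional-coverage averages, so results are independent of element
length) with fixed-resolution flanks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from promscape.genomic_io import FormatError, GenomeAssembly, PromoterWindow, RepeatElement


class CoverageTrack:
    """Per-chromosome stepwise non-negative coverage (bedGraph semantics)."""

    def __init__(self, data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # data[chrom] = (starts, ends, values) sorted, non-overlapping
        for chrom, (s, e, v) in data.items():
            if (v < 0).any():
                raise ValueError(f"negative coverage on {chrom}")
            if len(s) > 1 and (s[1:] < e[:-1]).any():
                raise ValueError(f"overlapping bedGraph intervals on {chrom}")
        self.data = data

    @classmethod
    def from_bedgraph(cls, path) -> "CoverageTrack":
        cols: Dict[str, List[Tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
                cols.setdefault(fields[0], []).append(
                    (int(fields[1]), int(fields[2]), float(fields[3]))
                )
        data = {}
        for chrom, rows in cols.items():
            rows.sort()
            arr = np.asarray(rows, dtype=float)
            data[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
        return cls(data)

    @classmethod
    def from_steps(cls, chrom_steps: Dict[str, Sequence[Tuple[int, int, float]]]):
        data = {}
        for chrom, rows in chrom_steps.items():
            rows = sorted(rows)
            data[chrom] = (
                np.asarray([r[0] for r in rows], dtype=np.int64),
                np.asarray([r[1] for r in rows], dtype=np.int64),
                np.asarray([r[2] for r in rows], dtype=float),
            )
        return cls(data)

    @classmethod
    def from_dense(cls, dense: Dict[str, np.ndarray]) -> "CoverageTrack":
        return cls({c: _dense_to_steps(np.asarray(v, dtype=float)) for c, v in dense.items()})

    def to_bedgraph(self, path):
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                s, e, v = self.data[chrom]
                for i in range(len(s)):
                    if v[i] != 0:
                        fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:g}\n")

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-bp values over [start, end); uncovered bases are 0."""
        out = np.zeros(end - start, dtype=float)
        tab = self.data.get(chrom)
        if tab is None:
            return out
        s, e, v = tab
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        for i in range(lo, hi):
            a = max(s[i], start) - start
            b = min(e[i], end) - start
            if b > a:
                out[a:b] = v[i]
        return out

    def add(self, other: "CoverageTrack", chrom_lengths: Dict[str, int]) -> "CoverageTrack":
        """Pointwise sum of two tracks (dense per chromosome; small genomes only)."""
        data = {}
        for chrom, L in chrom_lengths.items():
            dense = self.window(chrom, 0, L) + other.window(chrom, 0, L)
            data[chrom] = _dense_to_steps(dense)
        return CoverageTrack(data)


def _dense_to_steps(dense: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    change = np.flatnonzero(np.diff(dense) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(dense)]])
    vals = dense[starts]
    keep = vals != 0
    return starts[keep].astype(np.int64), ends[keep].astype(np.int64), vals[keep]


@dataclass
class MetaProfile:
    """Per-offset mean/variance of coverage over a set of oriented anchors."""

    anchor_set: str
    offsets: np.ndarray  # -flank .. flank-1
    mean: np.ndarray
    var: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    n_anchors: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                offset=self.offsets,
                mean=self.mean,
                var=self.var,
                band_lo=self.band_lo,
                band_hi=self.band_hi,
            )
        )


@dataclass
class ScaledMetaProfile:
    """Element-centred profile: fixed-resolution flanks + length-rescaled body."""

    anchor_set: str
    flank5_mean: np.ndarray
    body_mean: np.ndarray
    flank3_mean: np.ndarray
    flank: int
    flank_bin_size: int
    body_bins: int
    n_elements: int

    def concat(self) -> np.ndarray:
        return np.concatenate([self.flank5_mean, self.body_mean, self.flank3_mean])


def compute_tss_profile(
    track: CoverageTrack,
    promoters: Sequence[PromoterWindow],
    genome: GenomeAssembly,
    flank: int = 3000,
    clipped: str = "exclude",
    anchor_set: str = "tss",
) -> MetaProfile:
    """Average coverage around TSSs with a normal-approximation 95% band.

    Offset 0 is the TSS base itself on both strands: a + strand anchor
    reads genomic [tss - flank, tss + flank), a - strand anchor reads
    [tss - flank + 1, tss + flank + 1) reversed, so "downstream" is always
    transcription-downstream and genome mirroring is an exact symmetry.
    Windows truncated by chromosome ends are excluded by default
    (``clipped='zero_pad'`` keeps them, padding missing bases with 0).
    The band is mean +/- 1.96*sqrt(var/n) per offset (variance across
    anchors, ddof=1).
    """
    if clipped not in ("exclude", "zero_pad"):
        raise ValueError("clipped must be 'exclude' or 'zero_pad'")
    width = 2 * flank
    total = np.zeros(width)
    total_sq = np.zeros(width)
    n = 0
    for w in promoters:
        if w.strand == "-":
            lo, hi = w.tss - flank + 1, w.tss + flank + 1
        else:
            lo, hi = w.tss - flank, w.tss + flank
        L = genome.length(w.chrom)
        if lo < 0 or hi > L:
            if clipped == "exclude":
                continue
            a, b = max(0, lo), min(L, hi)
            vals = np.zeros(width)
            vals[a - lo : a - lo + (b - a)] = track.window(w.chrom, a, b)
        else:
            vals = track.window(w.chrom, lo, hi)
        if w.strand == "-":
            vals = vals[::-1]
        total += vals
        total_sq += vals * vals
        n += 1
    if n == 0:
        raise ValueError("no usable anchors")
    mean = total / n
    if n > 1:
        var = (total_sq - n * mean * mean) / (n - 1)
        var = np.maximum(var, 0.0)
    else:
        var = np.zeros(width)
    half = 1.96 * np.sqrt(var / n)
    return MetaProfile(
        anchor_set=anchor_set,
        offsets=np.arange(-flank, flank),
        mean=mean,
        var=var,
        band_lo=mean - half,
        band_hi=mean + half,
        n_anchors=n,
    )


def cluster_profile_shapes(
    profiles: pd.DataFrame,
    cut_height: float = 65.0,
    metric: str = "euclidean",
    method: str = "complete",
    normalize: bool = False,
) -> pd.Series:
    """Flat cluster labels for per-DBP mean profile vectors.

    Hierarchical clustering (default Euclidean, complete linkage) cut at
    ``cut_height``; with ``normalize=True`` each profile is scaled to unit
    maximum first.  Labels are renumbered by first appearance.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    X = profiles.to_numpy(dtype=float)
    if normalize:
        mx = np.abs(X).max(axis=1, keepdims=True)
        mx[mx == 0] = 1.0
        X = X / mx
    Z = linkage(pdist(X, metric=metric), method=method)
    labels = fcluster(Z, t=cut_height, criterion="distance")
    from promscape.occupancy import _relabel_by_first_appearance

    return pd.Series(
        _relabel_by_first_appearance(labels), index=profiles.index, name="cluster"
    )


def _stepwise_bin_means(vals: np.ndarray, n_bins: int) -> np.ndarray:
    """Exact means of a per-bp step function over n_bins equal fractional bins."""
    L = len(vals)
    cum = np.concatenate([[0.0], np.cumsum(vals)])
    edges = np.linspace(0.0, L, n_bins + 1)
    F = np.interp(edges, np.arange(L + 1), cum)
    return np.diff(F) / (L / n_bins)


def compute_element_profile(
    track: CoverageTrack,
    elements: Sequence[RepeatElement],
    genome: GenomeAssembly,
    flank: int = 5000,
    body_bins: int = 100,
    flank_bin_size: int = 50,
    anchor_set: str = "elements",
) -> ScaledMetaProfile:
    """Strand-aware scaled profile across elements of varying length.

    Each element body is rescaled to ``body_bins`` bins using exact
    fractional averages of the stepwise coverage; flanks are binned at
    ``flank_bin_size`` bp.  Elements whose flanked window leaves the
    chromosome are excluded.
    """
    if flank % flank_bin_size != 0:
        raise ValueError("flank must be a multiple of flank_bin_size")
    if not elements:
        raise ValueError("no elements given")
    n_fbins = flank // flank_bin_size
    sum5 = np.zeros(n_fbins)
    sum_body = np.zeros(body_bins)
    sum3 = np.zeros(n_fbins)
    n = 0
    for el in elements:
        L = genome.length(el.chrom)
        if el.start - flank < 0 or el.end + flank > L:
            continue
        up = track.window(el.chrom, el.start - flank, el.start)
        body = track.window(el.chrom, el.start, el.end)
        down = track.window(el.chrom, el.end, el.end + flank)
        if el.strand == "-":
            up, down = down[::-1], up[::-1]
            body = body[::-1]
        sum5 += up.reshape(n_fbins, flank_bin_size).mean(axis=1)
        sum_body += _stepwise_bin_means(body, body_bins)
        sum3 += down.reshape(n_fbins, flank_bin_size).mean(axis=1)
        n += 1
    if n == 0:
        raise ValueError("no usable elements (all clipped by chromosome ends)")
    return ScaledMetaProfile(
        anchor_set=anchor_set,
        flank5_mean=sum5 / n,
        body_mean=sum_body / n,
        flank3_mean=sum3 / n,
        flank=flank,
        flank_bin_size=flank_bin_size,
        body_bins=body_bins,
        n_elements=n,
    )
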