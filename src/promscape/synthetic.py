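"""Synthetic genomes with planted ground truth for end-to-end testing.

The generator emulates the statistical structure of a one-cell-state,
many-DBP ChIP-seq compendium: per-DBP replicate peak sets with controlled
reproducibility, an mRNA/lncRNA gene annotation on a small genome, a
log-linear binding→expression relationship, planted reservoir promoters
(ghost and zombie subtypes), one repeat family bound by a dedicated
three-DBP subset, super-enhancer intervals, and coverage tracks consistent
with the peak files.  Everything is deterministic given the master seed,
and every planted label is recorded in a manifest so recovery can be
scored exactly.

Default scale: 2 chromosomes x 10 Mb, 1,000 genes (30% lncRNA), 40 DBPs x
2 replicates, 200 copies of the planted repeat family -- large enough for
stable statistics, small enough to run end-to-end in well under five
minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from promscape._rng import substream
from promscape.expression import CountsTable, ExpressionMatrix, tpm_from_counts
from promscape.genomic_io import (
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    Peak,
    PromoterWindow,
    RepeatElement,
    extract_promoters,
)
from promscape.intervals import merge_arrays
from promscape.profiles import CoverageTrack


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the reference study conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 1000
    lncrna_fraction: float = 0.3
    n_dbps: int = 40
    replicates_per_dbp: int = 2
    # peak width ~ lognormal(mu, sigma) clipped to [min, max]
    peak_width_mu: float = 5.7  # exp(5.7) ~ 300 bp
    peak_width_sigma: float = 0.35
    peak_width_min: int = 100
    peak_width_max: int = 1000
    # replicate model
    jitter_max_shift: int = 20
    dropout_prob: float = 0.0
    # binding model: bimodal per-promoter target DBP count
    target_low_mean: float = 3.0
    target_high_mean: float = 15.0
    target_high_fraction: float = 0.25
    background_peaks_per_dbp: int = 150
    # expression model: log10(TPM + eps) = slope * n_dbps + Normal(0, sd)
    expr_slope: float = 0.1
    expr_noise_sd: float = 0.5
    tpm_eps: float = 0.001
    nonreservoir_high_tpm_floor: float = 0.011
    # reservoirs
    n_reservoirs: int = 50
    ghost_fraction: float = 0.6
    reservoir_min_dbps: int = 12
    reservoir_max_dbps: int = 30
    n_reservoirs_near_expressed: int = 15
    # planted repeat family (one family with a dedicated binder subset)
    planted_family: str = "SVA"
    planted_family_class: str = "Retroposon"
    planted_family_copies: int = 200
    planted_family_length: Tuple[int, int] = (800, 2000)
    n_family_binders: int = 3
    # decoy repeat families: (family, class, copies, (min_len, max_len))
    decoy_families: Tuple[Tuple[str, str, int, Tuple[int, int]], ...] = (
        ("L1", "LINE", 150, (1000, 3000)),
        ("Alu", "SINE", 300, (250, 350)),
        ("MIR", "SINE", 150, (100, 300)),
    )
    # super-enhancers
    n_superenhancers: int = 20
    se_host_tpm_floor: float = 30.0
    # sequencing
    rna_total_samples: int = 2
    polya_samples: int = 3
    proseq_samples: int = 2
    reads_per_sample: int = 60_000
    read_length: int = 100
    zombie_reads_per_sample: int = 20
    counts_scale: float = 1.0  # expected gene counts per TPM*kb
    promoter_flank: int = 3000

    def __post_init__(self):
        if not 0 <= self.lncrna_fraction <= 1 or not 0 <= self.ghost_fraction <= 1:
            raise ValueError("fractions must be in [0, 1]")
        for name in ("n_chromosomes", "chrom_length", "n_genes", "n_dbps",
                     "replicates_per_dbp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_reservoirs_near_expressed > self.n_reservoirs:
            raise ValueError("n_reservoirs_near_expressed exceeds n_reservoirs")


@dataclass
class SyntheticDataset:
    """In-memory view of one simulated study plus its ground-truth manifest."""

    config: SimulationConfig
    genome: GenomeAssembly
    genes: List[GeneModel]
    promoters: List[PromoterWindow]
    repeats: List[RepeatElement]
    superenhancers: List[GenomicInterval]
    dbp_names: List[str]
    family_binders: List[str]
    peaksets: Dict[str, List[List[Peak]]]  # dbp -> [replicate -> peaks]
    planted_gene_dbps: Dict[str, Tuple[str, ...]]
    background_peaks: Dict[str, List[GenomicInterval]]
    gene_counts: CountsTable  # gene-level counts, total+polyA samples
    gene_tpm: ExpressionMatrix  # planted per-sample gene TPM (total+polyA)
    reads: Dict[str, List[GenomicInterval]]  # per-sample read intervals
    read_assays: Dict[str, str]
    tracks: Dict[str, CoverageTrack]
    manifest: pd.DataFrame  # per-gene ground truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def simulate_annotation(config: SimulationConfig):
    """Genome, gene models, repeats, super-enhancers and the gene manifest."""
    rng = substream(config.seed, "annotation")
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = GenomeAssembly(
        {c: config.chrom_length for c in chrom_names},
        canonical=frozenset(chrom_names),
    )

    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    spacing = config.chrom_length // (per_chrom + 1)
    if spacing < 2 * config.promoter_flank + 10_000:
        raise ValueError("genome too small for requested number of genes")

    records = []
    gene_idx = 0
    for chrom in chrom_names:
        for slot in range(per_chrom):
            if gene_idx >= config.n_genes:
                break
            tss = spacing * (slot + 1)
            length = int(rng.integers(3000, 8001))
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(dict(
                gene_id=f"G{gene_idx:05d}", chrom=chrom, tss=tss,
                length=length, strand=strand,
            ))
            gene_idx += 1

    n_lnc = int(round(config.lncrna_fraction * len(records)))
    lnc_ids = set(rng.choice(len(records), size=n_lnc, replace=False).tolist())
    for i, rec in enumerate(records):
        rec["biotype"] = "lncRNA" if i in lnc_ids else "mRNA"

    # planted classes
    res_ids = rng.choice(len(records), size=config.n_reservoirs, replace=False)
    res_set = set(int(i) for i in res_ids)
    n_ghost = int(round(config.ghost_fraction * config.n_reservoirs))
    ghost_set = set(int(i) for i in res_ids[:n_ghost])
    for i, rec in enumerate(records):
        if i in ghost_set:
            rec["planted_class"] = "reservoir_ghost"
        elif i in res_set:
            rec["planted_class"] = "reservoir_zombie"
        else:
            rec["planted_class"] = "normal"
        rec["planted_tpm_floor"] = np.nan
        rec["se_host"] = False
        rec["near_expressed_host"] = ""

    normal_idx = [i for i in range(len(records)) if i not in res_set]

    # super-enhancer hosts: expressed normal genes
    se_hosts = rng.choice(len(normal_idx), size=config.n_superenhancers, replace=False)
    se_host_idx = [normal_idx[int(i)] for i in se_hosts]
    for i in se_host_idx:
        records[i]["se_host"] = True
        records[i]["planted_tpm_floor"] = config.se_host_tpm_floor

    # relocate some reservoirs right downstream of an expressed host gene so
    # that neighbouring transcription leaks into their promoter window
    # (these reservoirs will NOT be in the conservative set)
    candidates = [i for i in normal_idx if not records[i]["se_host"]]
    host_pick = rng.choice(len(candidates), size=config.n_reservoirs_near_expressed,
                           replace=False)
    relocated = sorted(res_set)[: config.n_reservoirs_near_expressed]
    for res_i, cand_j in zip(relocated, host_pick):
        host = records[candidates[int(cand_j)]]
        host["length"] = max(host["length"], 5000)
        host["planted_tpm_floor"] = max(
            float(host["planted_tpm_floor"]) if np.isfinite(host["planted_tpm_floor"]) else 0.0,
            50.0,
        )
        res = records[res_i]
        res["chrom"] = host["chrom"]
        res["strand"] = host["strand"]
        res["length"] = 2000
        if host["strand"] == "+":
            host_end = host["tss"] + host["length"]
            res["tss"] = host_end + 2000
        else:
            host_start = host["tss"] - host["length"] + 1
            res["tss"] = host_start - 2000
        res["near_expressed_host"] = host["gene_id"]

    genes: List[GeneModel] = []
    for rec in records:
        if rec["strand"] == "+":
            span = GenomicInterval(rec["chrom"], rec["tss"], rec["tss"] + rec["length"], "+")
        else:
            span = GenomicInterval(
                rec["chrom"], rec["tss"] - rec["length"] + 1, rec["tss"] + 1, "-"
            )
        genes.append(GeneModel(rec["gene_id"], rec["biotype"], span))

    promoters = extract_promoters(genes, genome, flank=config.promoter_flank)

    # promoter exclusion zones for repeat/background placement
    zones: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    margin = config.jitter_max_shift + 200
    for chrom in chrom_names:
        ivs = [(w.start - margin, w.end + margin) for w in promoters if w.chrom == chrom]
        if not ivs:
            zones[chrom] = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
            continue
        arr = np.asarray(sorted(ivs), dtype=np.int64)
        zones[chrom] = merge_arrays(np.maximum(arr[:, 0], 0), arr[:, 1])

    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_names}

    def place_clear(length: int, rng_local) -> GenomicInterval:
        # rejection-sample an interval clear of promoter windows and other repeats
        for _ in range(2000):
            chrom = chrom_names[int(rng_local.integers(config.n_chromosomes))]
            start = int(rng_local.integers(0, config.chrom_length - length))
            end = start + length
            zs, ze = zones[chrom]
            i = int(np.searchsorted(zs, end, side="left")) - 1
            if i >= 0 and len(ze) and ze[i] > start:
                continue
            if any(s < end and start < e for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            strand = "+" if rng_local.random() < 0.5 else "-"
            return GenomicInterval(chrom, start, end, strand)
        raise RuntimeError("could not place interval away from promoters")

    repeats: List[RepeatElement] = []
    rng_rep = substream(config.seed, "repeats")
    fams = [(config.planted_family, config.planted_family_class,
             config.planted_family_copies, config.planted_family_length)]
    fams += list(config.decoy_families)
    for fam, cls, copies, (lo, hi) in fams:
        for k in range(copies):
            length = int(rng_rep.integers(lo, hi + 1))
            iv = place_clear(length, rng_rep)
            repeats.append(RepeatElement(iv, f"{fam}_{k}", fam, cls))

    superenhancers: List[GenomicInterval] = []
    for i in se_host_idx:
        rec = records[i]
        lo = max(0, rec["tss"] - 5000)
        hi = min(config.chrom_length, rec["tss"] + 10_000)
        superenhancers.append(GenomicInterval(rec["chrom"], lo, hi))

    manifest = pd.DataFrame(records).set_index("gene_id")
    return genome, genes, promoters, repeats, superenhancers, manifest


# ---------------------------------------------------------------------------
# peak sets
# ---------------------------------------------------------------------------


def simulate_peaksets(
    config: SimulationConfig,
    genome: GenomeAssembly,
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatElement],
    manifest: pd.DataFrame,
):
    """Per-DBP replicate peak sets implementing the planted binding model.

    Every promoter receives one peak from each DBP of its planted set;
    background peaks are scattered away from promoter windows; the planted
    repeat family's binder DBPs get one peak per family copy.  Replicates
    are jittered copies of the planted peaks (uniform shift <= max shift,
    dropped with the dropout probability).
    """
    rng = substream(config.seed, "peaks")
    dbp_names = [f"DBP{i + 1:02d}" for i in range(config.n_dbps)]
    binders = dbp_names[-config.n_family_binders:]
    affinity = rng.dirichlet(np.ones(config.n_dbps) * 2.0)

    def draw_width() -> int:
        w = int(np.exp(rng.normal(config.peak_width_mu, config.peak_width_sigma)))
        return int(np.clip(w, config.peak_width_min, config.peak_width_max))

    manifest = manifest.copy()
    manifest["planted_n_dbps"] = 0
    manifest["planted_dbps"] = ""

    base_peaks: Dict[str, List[Tuple[GenomicInterval, str]]] = {d: [] for d in dbp_names}
    planted_gene_dbps: Dict[str, Tuple[str, ...]] = {}

    for gene in genes:
        rec = manifest.loc[gene.gene_id]
        if rec["planted_class"] != "normal":
            n_target = min(
                int(rng.integers(config.reservoir_min_dbps,
                                 config.reservoir_max_dbps + 1)),
                config.n_dbps,
            )
        else:
            if rng.random() < config.target_high_fraction:
                n_target = int(rng.poisson(config.target_high_mean))
            else:
                n_target = int(rng.poisson(config.target_low_mean))
            n_target = min(n_target, config.n_dbps)
        if n_target == 0:
            planted_gene_dbps[gene.gene_id] = ()
            continue
        chosen = rng.choice(config.n_dbps, size=n_target, replace=False, p=affinity)
        chosen_names = tuple(dbp_names[int(c)] for c in sorted(chosen))
        planted_gene_dbps[gene.gene_id] = chosen_names
        manifest.loc[gene.gene_id, "planted_n_dbps"] = n_target
        manifest.loc[gene.gene_id, "planted_dbps"] = ",".join(chosen_names)
        for name in chosen_names:
            w = draw_width()
            center = gene.tss + int(rng.integers(-2000, 2001))
            start = max(0, center - w // 2)
            end = min(genome.length(gene.chrom), start + w)
            base_peaks[name].append(
                (GenomicInterval(gene.chrom, start, end), "planted")
            )

    # planted repeat-family binding
    for name in binders:
        for el in repeats:
            if el.family != config.planted_family:
                continue
            w = min(draw_width(), el.interval.width)
            offset = int(rng.integers(0, el.interval.width - w + 1))
            base_peaks[name].append(
                (GenomicInterval(el.chrom, el.start + offset, el.start + offset + w),
                 "family"),
            )

    # background peaks away from promoter windows
    margin = config.jitter_max_shift + 5
    prom_zones: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genome.names:
        ivs = []
        for g in genes:
            if g.chrom != chrom:
                continue
            t = g.tss
            ivs.append((max(0, t - config.promoter_flank - margin),
                        t + config.promoter_flank + margin))
        if not ivs:
            prom_zones[chrom] = (
                np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
            )
            continue
        arr = np.asarray(sorted(ivs), dtype=np.int64)
        prom_zones[chrom] = merge_arrays(arr[:, 0], arr[:, 1])

    background: Dict[str, List[GenomicInterval]] = {d: [] for d in dbp_names}
    for name in dbp_names:
        n_bg = int(rng.poisson(config.background_peaks_per_dbp))
        placed = 0
        while placed < n_bg:
            chrom = genome.names[int(rng.integers(config.n_chromosomes))]
            w = draw_width()
            start = int(rng.integers(0, genome.length(chrom) - w))
            zs, ze = prom_zones[chrom]
            i = np.searchsorted(zs, start + w, side="left") - 1
            if i >= 0 and ze[i] > start:
                continue
            iv = GenomicInterval(chrom, start, start + w)
            base_peaks[name].append((iv, "background"))
            background[name].append(iv)
            placed += 1

    # replicate realisation: jitter + dropout
    peaksets: Dict[str, List[List[Peak]]] = {}
    for name in dbp_names:
        reps: List[List[Peak]] = []
        for r in range(1, config.replicates_per_dbp + 1):
            rep_peaks: List[Peak] = []
            for iv, _tag in base_peaks[name]:
                if config.dropout_prob > 0 and rng.random() < config.dropout_prob:
                    continue
                shift = int(rng.integers(-config.jitter_max_shift,
                                         config.jitter_max_shift + 1))
                start = max(0, iv.start + shift)
                end = min(genome.length(iv.chrom), iv.end + shift)
                score = float(np.round(rng.uniform(1, 10), 3))
                rep_peaks.append(
                    Peak(GenomicInterval(iv.chrom, start, end), name, r, score)
                )
            rep_peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
            reps.append(rep_peaks)
        peaksets[name] = reps

    return dbp_names, binders, peaksets, planted_gene_dbps, background, manifest


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _planted_tpm(config: SimulationConfig, manifest: pd.DataFrame, rng) -> np.ndarray:
    """Planted per-gene 'true' TPM (one draw; per-sample noise added later)."""
    n = manifest["planted_n_dbps"].to_numpy(dtype=float)
    noise = rng.normal(0.0, config.expr_noise_sd, size=len(manifest))
    tpm = np.power(10.0, config.expr_slope * n + noise) - config.tpm_eps
    tpm = np.maximum(tpm, 0.0)
    is_res = manifest["planted_class"].str.startswith("reservoir").to_numpy()
    tpm[is_res] = 0.0
    floor = manifest["planted_tpm_floor"].to_numpy(dtype=float)
    has_floor = np.isfinite(floor)
    tpm[has_floor] = np.maximum(tpm[has_floor], floor[has_floor])
    return tpm


def simulate_expression(
    config: SimulationConfig,
    genome: GenomeAssembly,
    genes: Sequence[GeneModel],
    manifest: pd.DataFrame,
):
    """Counts, per-sample TPM and read intervals for all assays.

    Normal genes follow log10(TPM + eps) = slope * n_dbps + Normal(0, sd);
    reservoirs have zero RNA in every total/polyA sample; zombies get a
    fixed nascent read dose in the promoter window while ghosts get none.
    Per-sample TPM columns are renormalised to sum to exactly 1e6, with
    non-reservoir promoters above the binding threshold floored away from
    the 'off' boundary so the planted margins survive renormalisation.
    """
    rng = substream(config.seed, "expression")
    gene_ids = [g.gene_id for g in genes]
    manifest = manifest.loc[gene_ids]
    lengths = pd.Series({g.gene_id: g.span.width for g in genes})
    base_tpm = _planted_tpm(config, manifest, rng)
    is_res = manifest["planted_class"].str.startswith("reservoir").to_numpy()
    high_nonres = (~is_res) & (manifest["planted_n_dbps"].to_numpy() > 7)

    samples = (
        [(f"total_{i + 1}", "total_rna") for i in range(config.rna_total_samples)]
        + [(f"polya_{i + 1}", "polya_rna") for i in range(config.polya_samples)]
    )
    tpm_cols = {}
    for sample, _assay in samples:
        rep_noise = np.exp(rng.normal(0.0, 0.1, size=len(gene_ids)))
        t = base_tpm * rep_noise
        t[is_res] = 0.0
        t = t * 1e6 / t.sum()
        t[high_nonres] = np.maximum(t[high_nonres], config.nonreservoir_high_tpm_floor)
        t = t * 1e6 / t.sum()  # exact column-sum invariant
        tpm_cols[sample] = t
    tpm_df = pd.DataFrame(tpm_cols, index=gene_ids)
    assays = {s: a for s, a in samples}
    gene_tpm = ExpressionMatrix(tpm_df, dict(assays))

    # gene-level counts consistent with the planted TPM (counts ~ TPM * length)
    counts = {}
    for sample, _assay in samples:
        lam = tpm_df[sample].to_numpy() * lengths.to_numpy() * config.counts_scale / 1e3
        counts[sample] = rng.poisson(lam)
    gene_counts = CountsTable(
        pd.DataFrame(counts, index=gene_ids), lengths, dict(assays)
    )

    # read intervals: RNA reads across gene spans, PRO-seq reads in windows
    reads: Dict[str, List[GenomicInterval]] = {}
    read_assays: Dict[str, str] = dict(assays)
    span_by_gene = {g.gene_id: g.span for g in genes}
    rl = config.read_length
    for sample, _assay in samples:
        lam = tpm_df[sample].to_numpy() * config.reads_per_sample / 1e6
        n_reads = rng.poisson(lam)
        ivs: List[GenomicInterval] = []
        for gid, k in zip(gene_ids, n_reads):
            if k == 0:
                continue
            span = span_by_gene[gid]
            hi = max(span.start + 1, span.end - rl)
            starts = rng.integers(span.start, hi, size=k)
            for s in starts:
                ivs.append(GenomicInterval(span.chrom, int(s), int(s) + rl))
        reads[sample] = ivs

    flank = config.promoter_flank
    tss = {g.gene_id: (g.chrom, g.tss) for g in genes}
    # nascent read budget follows the (renormalised) expression scale so the
    # zombie dose stays comparable to ordinary active promoters
    scaled = base_tpm * 1e6 / base_tpm.sum()
    pro_lam = scaled * config.reads_per_sample / 1e6
    is_zombie = (manifest["planted_class"] == "reservoir_zombie").to_numpy()
    for i in range(config.proseq_samples):
        sample = f"proseq_{i + 1}"
        read_assays[sample] = "pro_seq"
        n_reads = rng.poisson(pro_lam)
        n_reads[is_res] = 0
        n_reads[is_zombie] = config.zombie_reads_per_sample
        ivs = []
        for gid, k in zip(gene_ids, n_reads):
            if k == 0:
                continue
            chrom, t = tss[gid]
            lo = max(0, t - flank)
            hi = min(genome.length(chrom) - rl, t + flank - rl)
            starts = rng.integers(lo, max(lo + 1, hi), size=k)
            for s in starts:
                ivs.append(GenomicInterval(chrom, int(s), int(s) + rl))
        reads[sample] = ivs

    manifest = manifest.copy()
    manifest["planted_tpm"] = base_tpm
    return gene_counts, gene_tpm, reads, read_assays, manifest


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def _pileup_steps(intervals: Sequence[GenomicInterval]):
    """Stepwise pileup (sum of indicator functions) of possibly-overlapping intervals."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    data = {}
    for chrom, pairs in by_chrom.items():
        edges = []
        for s, e in pairs:
            edges.append((s, 1))
            edges.append((e, -1))
        edges.sort()
        steps = []
        depth = 0
        prev = None
        for pos, delta in edges:
            if prev is not None and pos > prev and depth > 0:
                steps.append((prev, pos, float(depth)))
            depth += delta
            prev = pos
        # merge adjacent equal-depth steps
        merged: List[Tuple[int, int, float]] = []
        for s, e, v in steps:
            if merged and merged[-1][1] == s and merged[-1][2] == v:
                merged[-1] = (merged[-1][0], e, v)
            else:
                merged.append((s, e, v))
        data[chrom] = (
            np.asarray([m[0] for m in merged], dtype=np.int64),
            np.asarray([m[1] for m in merged], dtype=np.int64),
            np.asarray([m[2] for m in merged], dtype=float),
        )
    return data


def simulate_coverage(
    config: SimulationConfig,
    genome: GenomeAssembly,
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatElement],
    peaksets: Dict[str, List[List[Peak]]],
    manifest: pd.DataFrame,
) -> Dict[str, CoverageTrack]:
    """Coverage tracks consistent with the peak files plus histone-mark proxies.

    Per-DBP tracks are the pileup of all replicate peaks (so coverage >= 1
    under every emitted peak).  An H3K4me1-like track ramps from high at
    the 5' end to low at the 3' end of each planted-family copy; an
    H3K27ac-like track marks expressed promoters and an H3K27me3-like
    track marks silent ones.
    """
    tracks: Dict[str, CoverageTrack] = {}
    for dbp, reps in peaksets.items():
        ivs = [p.interval for rep in reps for p in rep]
        tracks[dbp] = CoverageTrack(_pileup_steps(ivs))

    # H3K4me1-like: 5'-skewed ramp over each planted-family element
    k4_steps: Dict[str, List[Tuple[int, int, float]]] = {}
    n_ramp = 10
    for el in repeats:
        if el.family != config.planted_family:
            continue
        L = el.interval.width
        edges = np.linspace(el.start, el.end, n_ramp + 1).astype(int)
        heights = np.linspace(2.0, 0.2, n_ramp)
        if el.strand == "-":
            heights = heights[::-1]
        for i in range(n_ramp):
            if edges[i + 1] > edges[i]:
                k4_steps.setdefault(el.chrom, []).append(
                    (int(edges[i]), int(edges[i + 1]), float(heights[i]))
                )
    tracks["H3K4me1"] = CoverageTrack.from_steps(k4_steps)

    expressed = manifest["planted_tpm"] >= 1.0
    # the heterochromatic proxy marks promoters with neither mature nor
    # nascent output, i.e. the planted ghosts
    silent = manifest["planted_class"] == "reservoir_ghost"
    ac_steps: Dict[str, List[Tuple[int, int, float]]] = {}
    me3_steps: Dict[str, List[Tuple[int, int, float]]] = {}
    for g in genes:
        lo = max(0, g.tss - 1000)
        hi = min(genome.length(g.chrom), g.tss + 1000)
        if expressed.loc[g.gene_id]:
            ac_steps.setdefault(g.chrom, []).append((lo, hi, 1.0))
        elif silent.loc[g.gene_id]:
            me3_steps.setdefault(g.chrom, []).append((lo, hi, 1.0))
    tracks["H3K27ac"] = CoverageTrack.from_steps(ac_steps)
    tracks["H3K27me3"] = CoverageTrack.from_steps(me3_steps)
    return tracks


# ---------------------------------------------------------------------------
# orchestration + serialisation
# ---------------------------------------------------------------------------


def simulate_all(
    config: Optional[SimulationConfig] = None,
    outdir: Optional[Path] = None,
    with_coverage: bool = True,
) -> SyntheticDataset:
    """Run all generator stages; optionally write the full file bundle."""
    config = config or SimulationConfig()
    genome, genes, promoters, repeats, ses, manifest = simulate_annotation(config)
    (dbp_names, binders, peaksets, planted_gene_dbps,
     background, manifest) = simulate_peaksets(config, genome, genes, repeats, manifest)
    gene_counts, gene_tpm, reads, read_assays, manifest = simulate_expression(
        config, genome, genes, manifest
    )
    tracks = (
        simulate_coverage(config, genome, genes, repeats, peaksets, manifest)
        if with_coverage
        else {}
    )
    ds = SyntheticDataset(
        config=config,
        genome=genome,
        genes=genes,
        promoters=promoters,
        repeats=repeats,
        superenhancers=ses,
        dbp_names=dbp_names,
        family_binders=binders,
        peaksets=peaksets,
        planted_gene_dbps=planted_gene_dbps,
        background_peaks=background,
        gene_counts=gene_counts,
        gene_tpm=gene_tpm,
        reads=reads,
        read_assays=read_assays,
        tracks=tracks,
        manifest=manifest,
    )
    if outdir is not None:
        write_dataset(ds, Path(outdir))
    return ds


def write_dataset(ds: SyntheticDataset, outdir: Path):
    """Serialise the dataset in exactly the formats the pipeline reads."""
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "reads").mkdir(exist_ok=True)
    (outdir / "coverage").mkdir(exist_ok=True)
    (outdir / "manifest").mkdir(exist_ok=True)

    with open(outdir / "genome.chrom.sizes", "w") as fh:
        for name in ds.genome.names:
            fh.write(f"{name}\t{ds.genome.length(name)}\n")

    with open(outdir / "genes.gtf", "w") as fh:
        gt = {"mRNA": "protein_coding", "lncRNA": "lncRNA"}
        for g in ds.genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{gt[g.biotype]}";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )

    with open(outdir / "repeats.tsv", "w") as fh:
        fh.write("genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\n")
        for r in ds.repeats:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.name}\t"
                f"{r.repeat_class}\t{r.family}\n"
            )

    with open(outdir / "superenhancers.bed", "w") as fh:
        for iv in ds.superenhancers:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    for dbp, reps in ds.peaksets.items():
        for r, peaks in enumerate(reps, 1):
            with open(outdir / "peaks" / f"{dbp}_rep{r}.broadPeak", "w") as fh:
                for i, p in enumerate(peaks):
                    fh.write(
                        f"{p.chrom}\t{p.start}\t{p.end}\t{dbp}_peak{i}\t0\t.\t"
                        f"{p.score:g}\t-1\t-1\n"
                    )

    for sample, ivs in ds.reads.items():
        with open(outdir / "reads" / f"{sample}.bed", "w") as fh:
            for iv in ivs:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    counts_df = ds.gene_counts.counts.copy()
    counts_df.insert(0, "length", ds.gene_counts.lengths)
    counts_df.to_csv(outdir / "gene_counts.tsv", sep="\t", index_label="gene_id")
    ds.gene_tpm.tpm.to_csv(outdir / "gene_tpm.tsv", sep="\t", index_label="gene_id",
                           float_format="%.6f")
    with open(outdir / "assays.tsv", "w") as fh:
        fh.write("sample\tassay\n")
        for s, a in sorted(ds.read_assays.items()):
            fh.write(f"{s}\t{a}\n")

    for name, track in ds.tracks.items():
        track.to_bedgraph(outdir / "coverage" / f"{name}.bedGraph")

    ds.manifest.to_csv(outdir / "manifest" / "genes.tsv", sep="\t")
    import yaml

    cfg = asdict(ds.config)
    cfg["planted_family_length"] = list(cfg["planted_family_length"])
    cfg["decoy_families"] = [list(map(list_or_scalar, f)) for f in cfg["decoy_families"]]
    with open(outdir / "manifest" / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def list_or_scalar(x):
    return list(x) if isinstance(x, tuple) else x
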