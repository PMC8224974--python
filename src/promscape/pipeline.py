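"""Configuration, orchestration and stage logic tying the analyses together.

The pipeline runs on a directory layout produced by the synthetic-data
generator (or assembled from equivalent real files): ``data/`` holds the
inputs, each stage writes its outputs under the run directory, and a run
manifest records the config snapshot, input checksums, seed and stage
timings.  Stages are independently runnable; each checks that its
upstream outputs exist.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from promscape import consensus as cns
from promscape import enrichment as enr
from promscape import expression as expr
from promscape import genomic_io as gio
from promscape import occupancy as occ
from promscape import profiles as prf
from promscape import reservoirs as res
from promscape.synthetic import SimulationConfig, simulate_all

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class AnalysisThresholds:
    """Every tunable cutoff of the analysis, with the reference defaults."""

    promoter_flank: int = 3000
    element_flank: int = 5000
    min_consensus_peaks: int = 250
    peak_percentile: float = 15.0
    n_permutations: int = 1000
    expression_bin_edges: tuple = (0.001, 0.137, 3.0)
    reservoir_min_dbps: int = 7
    reservoir_tpm: float = 0.001
    ghost_proseq_tpm: float = 0.001
    neighbor_distance: int = 1000
    window_genes: int = 5
    dbp_bias_p: float = 0.001
    dbp_bias_fold: float = 2.0
    profile_cut_height: float = 65.0

    def __post_init__(self):
        e = tuple(self.expression_bin_edges)
        if not all(a < b for a, b in zip(e, e[1:])) or e[0] <= 0:
            raise ValueError("expression bin edges must be positive and increasing")
        self.expression_bin_edges = e
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"threshold {f.name} must be positive")


@dataclass
class PipelineConfig:
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    #: coverage tracks to include in the profile stage besides per-DBP tracks
    mark_tracks: tuple = ("H3K4me1", "H3K27ac", "H3K27me3")
    #: DBP names counted as Pol II machinery for the polII_bound flag
    polii_dbps: tuple = ()

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))


def load_config(path: Optional[Path] = None, seed: Optional[int] = None) -> PipelineConfig:
    """Load a YAML config; unknown keys at any level are hard errors."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    version = raw.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version}")

    def build(cls, data, name):
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown keys in {name}: {sorted(unknown)}")
        return cls(**data)

    sim = build(SimulationConfig, raw.pop("simulation", {}), "simulation")
    thr = build(AnalysisThresholds, raw.pop("thresholds", {}), "thresholds")
    cfg_kwargs = dict(raw)
    unknown = set(cfg_kwargs) - {"seed", "simulate", "mark_tracks", "polii_dbps"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    cfg = PipelineConfig(simulation=sim, thresholds=thr, **cfg_kwargs)
    if seed is not None:
        cfg.seed = seed
        cfg.simulation.seed = seed
    else:
        cfg.simulation.seed = cfg.seed
    return cfg


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    def __init__(self, outdir: Path, config: PipelineConfig):
        self.path = Path(outdir) / "run_manifest.json"
        snapshot = config.snapshot()
        self.data = {
            "schema_version": SCHEMA_VERSION,
            "seed": config.seed,
            "config": snapshot,
            "config_hash": hashlib.sha256(
                json.dumps(snapshot, sort_keys=True).encode()
            ).hexdigest(),
            "input_checksums": {},
            "stages": {},
            "outputs": [],
        }
        self.write()

    def checksum_inputs(self, datadir: Path):
        sums = {}
        for p in sorted(Path(datadir).rglob("*")):
            if p.is_file():
                sums[str(p.relative_to(datadir))] = _sha256(p)
        self.data["input_checksums"] = sums
        self.write()

    def record_stage(self, name: str, seconds: float, outputs: Sequence[Path]):
        self.data["stages"][name] = {"seconds": round(seconds, 3)}
        self.data["outputs"].extend(str(o) for o in outputs)
        self.write()

    def write(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)


class MissingUpstream(RuntimeError):
    """A stage's upstream outputs are missing."""


def _require(path: Path, stage: str, hint: str) -> Path:
    if not Path(path).exists():
        raise MissingUpstream(
            f"stage '{stage}' requires {path} — run '{hint}' first"
        )
    return Path(path)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> Path:
    datadir = Path(outdir) / "data"
    simulate_all(cfg.simulation, outdir=datadir)
    return datadir


def _load_genome(outdir: Path, stage: str) -> gio.GenomeAssembly:
    path = _require(Path(outdir) / "data" / "genome.chrom.sizes", stage, "simulate")
    sizes = gio.read_genome(path)
    # synthetic chromosomes are all canonical
    return gio.GenomeAssembly(sizes.chroms, canonical=frozenset(sizes.chroms))


def stage_consensus(cfg: PipelineConfig, outdir: Path) -> Dict[str, cns.ConsensusPeakSet]:
    outdir = Path(outdir)
    genome = _load_genome(outdir, "consensus")
    peak_dir = _require(outdir / "data" / "peaks", "consensus", "simulate")
    by_dbp: Dict[str, Dict[int, Path]] = {}
    for p in sorted(peak_dir.glob("*_rep*.broadPeak")):
        dbp, rep = p.stem.rsplit("_rep", 1)
        by_dbp.setdefault(dbp, {})[int(rep)] = p
    cons_dir = outdir / "consensus"
    cons_dir.mkdir(exist_ok=True)
    sets = []
    for dbp in sorted(by_dbp):
        reps = []
        for r in sorted(by_dbp[dbp]):
            peaks = gio.read_peaks(by_dbp[dbp][r], dbp, r, genome)
            peaks, _ = cns.filter_canonical(peaks, genome)
            reps.append(peaks)
        sets.append(cns.build_consensus(reps, dbp))
    kept, reports = cns.filter_by_min_peaks(
        sets, cfg.thresholds.min_consensus_peaks, cfg.thresholds.peak_percentile
    )
    for s in kept:
        gio.write_bed(s.intervals, cons_dir / f"{s.dbp}.bed")
    pd.DataFrame(
        [dataclasses.asdict(r) for r in reports]
    ).to_csv(cons_dir / "filter_report.tsv", sep="\t", index=False)
    return {s.dbp: s for s in kept}


def _load_consensus(cfg: PipelineConfig, outdir: Path, stage: str):
    cons_dir = _require(Path(outdir) / "consensus", stage, "consensus")
    report = pd.read_csv(cons_dir / "filter_report.tsv", sep="\t")
    n_rep = 2
    sets = {}
    for bed in sorted(cons_dir.glob("*.bed")):
        ivs = gio.read_bed(bed)
        sets[bed.stem] = cns.ConsensusPeakSet(bed.stem, ivs, n_rep)
    if not sets:
        raise MissingUpstream(f"no consensus BEDs under {cons_dir}")
    return sets, report


def _load_annotation(cfg: PipelineConfig, outdir: Path, stage: str):
    genome = _load_genome(outdir, stage)
    gtf = _require(Path(outdir) / "data" / "genes.gtf", stage, "simulate")
    genes = gio.read_gtf_genes(gtf, genome)
    promoters = gio.extract_promoters(genes, genome, cfg.thresholds.promoter_flank)
    return genome, genes, promoters


def stage_occupancy(cfg: PipelineConfig, outdir: Path):
    outdir = Path(outdir)
    genome, genes, promoters = _load_annotation(cfg, outdir, "occupancy")
    sets, _ = _load_consensus(cfg, outdir, "occupancy")
    occ_dir = outdir / "occupancy"
    occ_dir.mkdir(exist_ok=True)
    matrix = occ.build_occupancy_matrix(list(sets.values()), promoters)
    matrix.to_tsv(occ_dir / "occupancy.tsv")

    biotype = {g.gene_id: g.biotype for g in genes}
    win_by_bt = {
        "all": promoters,
        "mRNA": [w for w in promoters if biotype[w.gene_id] == "mRNA"],
        "lncRNA": [w for w in promoters if biotype[w.gene_id] == "lncRNA"],
    }
    rows = []
    for bt, wins in win_by_bt.items():
        pts = [
            (s.n_peaks, occ.count_feature_overlaps(s, wins))
            for s in sets.values()
        ]
        fit = occ.fit_peaknum_regression(pts)
        rows.append(dict(subset=bt, **dataclasses.asdict(fit)))
    pd.DataFrame(rows).to_csv(occ_dir / "peaknum_regression.tsv", sep="\t", index=False)

    ann = occ.annotate_peak_features(
        [gio.Peak(iv, s.dbp, 1) for s in sets.values() for iv in s.intervals],
        genes,
        promoter_flank=cfg.thresholds.promoter_flank,
    )
    ann.to_csv(occ_dir / "feature_annotation.tsv", sep="\t", index_label="dbp")
    return matrix


def stage_enrich(cfg: PipelineConfig, outdir: Path):
    outdir = Path(outdir)
    genome, genes, promoters = _load_annotation(cfg, outdir, "enrich")
    sets, _ = _load_consensus(cfg, outdir, "enrich")
    enr_dir = outdir / "enrichment"
    enr_dir.mkdir(exist_ok=True)

    biotype = {g.gene_id: g.biotype for g in genes}
    feature_sets = {
        "promoters_all": [w.interval for w in promoters],
        "promoters_mRNA": [w.interval for w in promoters if biotype[w.gene_id] == "mRNA"],
        "promoters_lncRNA": [
            w.interval for w in promoters if biotype[w.gene_id] == "lncRNA"
        ],
    }
    nulls = []
    for dbp in sorted(sets):
        for fs_name, feats in feature_sets.items():
            nulls.append(
                enr.permutation_enrichment(
                    sets[dbp], feats, genome,
                    n_perm=cfg.thresholds.n_permutations,
                    seed=cfg.seed, feature_set=fs_name,
                )
            )
    enr.nulls_to_frame(nulls).to_csv(
        enr_dir / "promoter_enrichment.tsv", sep="\t", index=False
    )

    repeats = gio.read_repeats(_require(outdir / "data" / "repeats.tsv", "enrich", "simulate"))
    for by in ("family", "class"):
        z, p, _ = enr.repeat_enrichment_matrix(
            list(sets.values()), repeats, genome, by=by,
            n_perm=cfg.thresholds.n_permutations, seed=cfg.seed,
        )
        z.to_csv(enr_dir / f"repeat_{by}_z.tsv", sep="\t", index_label="dbp")
        p.to_csv(enr_dir / f"repeat_{by}_p.tsv", sep="\t", index_label="dbp")

    matrix = occ.OccupancyMatrix.from_tsv(
        _require(outdir / "occupancy" / "occupancy.tsv", "enrich", "occupancy")
    )
    bias = enr.biotype_bias_test(matrix, biotype)
    pd.DataFrame(
        [
            dict(dbp=b.dbp, log2_obs_exp=b.log2_obs_exp, chi2=b.statistic,
                 p=b.p, valid=b.valid)
            for b in bias
        ]
    ).to_csv(enr_dir / "biotype_bias.tsv", sep="\t", index=False)


def stage_profile(cfg: PipelineConfig, outdir: Path):
    outdir = Path(outdir)
    genome, genes, promoters = _load_annotation(cfg, outdir, "profile")
    cov_dir = _require(outdir / "data" / "coverage", "profile", "simulate")
    prof_dir = outdir / "profiles"
    prof_dir.mkdir(exist_ok=True)

    rows = {}
    for bg in sorted(cov_dir.glob("*.bedGraph")):
        track = prf.CoverageTrack.from_bedgraph(bg)
        mp = prf.compute_tss_profile(
            track, promoters, genome, flank=cfg.thresholds.promoter_flank,
            anchor_set=bg.stem,
        )
        rows[bg.stem] = mp.mean
    profile_df = pd.DataFrame.from_dict(rows, orient="index")
    profile_df.columns = np.arange(
        -cfg.thresholds.promoter_flank, cfg.thresholds.promoter_flank
    )
    profile_df.to_csv(prof_dir / "tss_profiles.tsv", sep="\t", index_label="track",
                      float_format="%.6g")
    labels = prf.cluster_profile_shapes(
        profile_df, cut_height=cfg.thresholds.profile_cut_height
    )
    labels.to_csv(prof_dir / "profile_clusters.tsv", sep="\t", index_label="track")

    # element-centred profiles over the most repeat-rich family for mark tracks
    repeats = gio.read_repeats(outdir / "data" / "repeats.tsv")
    fams = pd.Series([r.family for r in repeats]).value_counts()
    target_family = fams.index[0]
    elements = [r for r in repeats if r.family == target_family]
    for name in cfg.mark_tracks:
        bg = cov_dir / f"{name}.bedGraph"
        if not bg.exists():
            continue
        track = prf.CoverageTrack.from_bedgraph(bg)
        sp = prf.compute_element_profile(
            track, elements, genome, flank=cfg.thresholds.element_flank,
            anchor_set=f"{name}:{target_family}",
        )
        out = pd.DataFrame(
            dict(bin=np.arange(len(sp.concat())), mean=sp.concat())
        )
        out.to_csv(prof_dir / f"element_profile_{name}.tsv", sep="\t", index=False,
                   float_format="%.6g")


def stage_expression(cfg: PipelineConfig, outdir: Path):
    outdir = Path(outdir)
    genome, genes, promoters = _load_annotation(cfg, outdir, "expression")
    expr_dir = outdir / "expression"
    expr_dir.mkdir(exist_ok=True)
    assays = pd.read_csv(
        _require(outdir / "data" / "assays.tsv", "expression", "simulate"), sep="\t"
    ).set_index("sample")["assay"].to_dict()

    # gene-level TPM (as quantified upstream), averaged per assay
    tpm = pd.read_csv(outdir / "data" / "gene_tpm.tsv", sep="\t", index_col="gene_id")
    emat = expr.ExpressionMatrix(tpm, {s: assays[s] for s in tpm.columns})
    by_assay = emat.mean_by_assay()
    by_assay.to_csv(expr_dir / "gene_tpm_by_assay.tsv", sep="\t",
                    index_label="gene_id", float_format="%.6f")

    # promoter-window quantification (multi-overlap) for every read sample
    reads_dir = _require(outdir / "data" / "reads", "expression", "simulate")
    reads = {}
    for bed in sorted(reads_dir.glob("*.bed")):
        reads[bed.stem] = gio.read_bed(bed)
    counts = expr.quantify_window(reads, promoters, assays)
    wtpm = expr.tpm_from_counts(counts)
    wtpm.tpm.to_csv(expr_dir / "window_tpm.tsv", sep="\t", index_label="gene_id",
                    float_format="%.6f")

    matrix = occ.OccupancyMatrix.from_tsv(
        _require(outdir / "occupancy" / "occupancy.tsv", "expression", "occupancy")
    )
    n_dbps = matrix.n_dbps.reindex(by_assay.index)
    corr = expr.binding_expression_correlation(
        n_dbps.to_numpy(), by_assay["total_rna"].to_numpy()
    )
    pd.DataFrame([dataclasses.asdict(corr)]).to_csv(
        expr_dir / "binding_expression.tsv", sep="\t", index=False
    )

    bins = by_assay["total_rna"].map(
        lambda t: expr.classify_expression_bin(t, cfg.thresholds.expression_bin_edges)
    )
    bins.rename("expression_bin").to_csv(expr_dir / "expression_bins.tsv", sep="\t",
                                         index_label="gene_id")


def stage_reservoirs(cfg: PipelineConfig, outdir: Path):
    outdir = Path(outdir)
    genome, genes, promoters = _load_annotation(cfg, outdir, "reservoirs")
    thr = cfg.thresholds
    res_dir = outdir / "reservoirs"
    res_dir.mkdir(exist_ok=True)

    matrix = occ.OccupancyMatrix.from_tsv(
        _require(outdir / "occupancy" / "occupancy.tsv", "reservoirs", "occupancy")
    )
    by_assay = pd.read_csv(
        _require(outdir / "expression" / "gene_tpm_by_assay.tsv", "reservoirs",
                 "expression"),
        sep="\t", index_col="gene_id",
    )
    window_tpm = pd.read_csv(outdir / "expression" / "window_tpm.tsv", sep="\t",
                             index_col="gene_id")
    assays = pd.read_csv(outdir / "data" / "assays.tsv", sep="\t").set_index(
        "sample")["assay"].to_dict()

    biotype = {g.gene_id: g.biotype for g in genes}
    calls = res.call_reservoirs(
        matrix, by_assay["total_rna"], biotype,
        min_dbps=thr.reservoir_min_dbps, tpm_off=thr.reservoir_tpm,
    )
    if "polya_rna" in by_assay:
        calls["tpm_polya"] = by_assay["polya_rna"].reindex(calls.index)

    se = gio.read_bed(_require(outdir / "data" / "superenhancers.bed",
                               "reservoirs", "simulate"))
    calls, n_se = res.flag_superenhancer_overlap(calls, promoters, se)

    calls["neighbor_class"] = res.classify_neighbors(
        genes, thr.neighbor_distance
    ).reindex(calls.index)

    pro_cols = [s for s, a in assays.items() if a == "pro_seq" and s in window_tpm]
    proseq = window_tpm[pro_cols].mean(axis=1)
    calls = res.classify_ghost_zombie(calls, proseq, thr.ghost_proseq_tpm)

    rna_cols = [
        s for s, a in assays.items()
        if a in ("total_rna", "polya_rna") and s in window_tpm
    ]
    calls = res.conservative_set(calls, window_tpm[rna_cols], thr.reservoir_tpm)
    calls = res.flag_polii_bound(calls, matrix, cfg.polii_dbps)

    frac, chi2, chi_p, _ = res.neighbor_expression_status(
        calls, genes, by_assay["total_rna"], thr.neighbor_distance, thr.reservoir_tpm
    )
    windows_df, tests = res.window_neighborhood_expression(
        genes, by_assay["total_rna"], calls, k=thr.window_genes
    )
    calls["neighbor_mean_tpm"] = windows_df["neighbor_mean_tpm"].reindex(calls.index)

    enriched, depleted, bias_df = enr.reservoir_dbp_bias(
        matrix, calls["is_reservoir"].to_dict(), thr.dbp_bias_p, thr.dbp_bias_fold
    )
    bias_df.to_csv(res_dir / "reservoir_dbp_bias.tsv", sep="\t")

    bins = pd.read_csv(outdir / "expression" / "expression_bins.tsv", sep="\t",
                       index_col="gene_id")["expression_bin"]
    calls["expression_bin"] = bins.reindex(calls.index)

    # chromatin-state association: mark present <=> >=1 bp of non-zero mark
    # coverage inside the promoter window
    chromatin = {}
    for mark in ("H3K27ac", "H3K27me3"):
        bg = outdir / "data" / "coverage" / f"{mark}.bedGraph"
        if not bg.exists():
            continue
        from promscape import intervals as ivl
        from promscape.profiles import CoverageTrack

        track = CoverageTrack.from_bedgraph(bg)
        merged = {c: ivl.merge_arrays(s, e) for c, (s, e, _v) in track.data.items()}
        flags = {}
        for w in promoters:
            tab = merged.get(w.chrom)
            hit = False
            if tab is not None:
                hit = bool(ivl.overlaps_any(
                    np.array([w.start]), np.array([w.end]), tab[0], tab[1]
                )[0])
            flags[w.gene_id] = hit
        calls[f"{mark.lower()}_flag"] = pd.Series(flags).reindex(calls.index)
        chromatin[mark] = {
            "all_promoters": res.chromatin_association(flags, proseq.to_dict()),
            "reservoirs": res.chromatin_association(
                flags, proseq.to_dict(),
                subset=list(calls.index[calls["is_reservoir"]]),
            ),
        }

    n_res = int(calls["is_reservoir"].sum())
    k_lnc = int((calls["is_reservoir"] & (calls["biotype"] == "lncRNA")).sum())
    summary = dict(
        n_promoters=len(calls),
        n_reservoirs=n_res,
        n_ghosts=int((calls["subclass"] == "ghost").sum()),
        n_zombies=int((calls["subclass"] == "zombie").sum()),
        n_conservative=int(calls["conservative"].sum()),
        n_se_overlap_reservoirs=n_se,
        lncRNA_reservoirs=k_lnc,
        lncRNA_overrepresentation_p=enr.hypergeometric_overrepresentation(
            k_lnc, int((calls["biotype"] == "lncRNA").sum()), n_res, len(calls)
        ) if n_res else float("nan"),
        neighbor_expressed_fraction=frac,
        neighbor_chi2_p=chi_p,
        window_tests={k: {"stat": v[0], "p": v[1]} for k, v in tests.items()},
        dbp_bias_enriched=enriched,
        dbp_bias_depleted=depleted,
        chromatin=chromatin,
    )
    with open(res_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    calls.to_csv(res_dir / "master.tsv", sep="\t", float_format="%.6f")
    return calls, summary


STAGES = (
    ("simulate", stage_simulate),
    ("consensus", stage_consensus),
    ("occupancy", stage_occupancy),
    ("enrich", stage_enrich),
    ("profile", stage_profile),
    ("expression", stage_expression),
    ("reservoirs", stage_reservoirs),
)

_STAGE_MARKERS = {
    "simulate": "data/genome.chrom.sizes",
    "consensus": "consensus/filter_report.tsv",
    "occupancy": "occupancy/occupancy.tsv",
    "enrich": "enrichment/promoter_enrichment.tsv",
    "profile": "profiles/tss_profiles.tsv",
    "expression": "expression/window_tpm.tsv",
    "reservoirs": "reservoirs/master.tsv",
}


def run_pipeline(
    cfg: PipelineConfig, outdir: Path, resume: bool = False
) -> RunManifest:
    """Run all stages in dependency order; identical seed+inputs give identical outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(outdir, cfg)
    for name, fn in STAGES:
        marker = outdir / _STAGE_MARKERS[name]
        if resume and marker.exists():
            log.info("stage %s: cached, skipping", name)
            continue
        if name == "simulate" and not cfg.simulate:
            _require(outdir / "data", name, "provide a data/ directory")
            continue
        t0 = time.perf_counter()
        fn(cfg, outdir)
        manifest.record_stage(name, time.perf_counter() - t0, [marker])
        if name == "simulate":
            manifest.checksum_inputs(outdir / "data")
    return manifest
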