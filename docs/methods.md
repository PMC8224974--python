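# Methods

This note documents the models, conventions and design choices behind
promscape, what the synthetic-data generator does and does not emulate,
and the known limitations. All coordinates in the package are 0-based,
half-open (BED convention); GTF input is converted on read. Overlap
always means ≥ 1 bp.

## Consensus peaks

Replicate peaks of one DBP form an undirected graph with an edge wherever
two peaks share ≥ 1 bp. Each connected component containing at least one
peak from every replicate emits one consensus interval spanning the
component (`[min start, max end]`). Components are found with a
per-chromosome sweep (an interval joins the open component while its start
precedes the running maximum end), which is exactly the connected-component
relation for intervals and is independent of replicate order and peak
order. Transitive chains (A–B and B–C overlap, A–C do not) therefore
merge into a single consensus region; a strict mutual-overlap mode is
deliberately not offered, since the union-span rule is the one the rest of
the analysis depends on. A replicate with zero peaks makes the whole DBP
unreproducible.

The reproducibility filter keeps DBPs with
n ≥ max(min_peaks, P₁₅(n₁..n_D)), with min_peaks = 250 and the percentile
computed by the **nearest-rank (≤)** rule: the smallest observed value
with at least 15% of the distribution at or below it
(`sorted[ceil(0.15·D) − 1]`). Note the percentile arm removes the bottom
of the distribution *by construction*, at any data scale.

## Occupancy and simple fits

Binding is binary at the window level: any number of peaks of one DBP in
one TSS ± 3 kb window contributes a single 1. Peak-count regressions are
ordinary least squares with intercept (Pearson r, two-sided p on the
slope). Peak-to-feature annotation assigns each peak by its midpoint with
fixed precedence promoter/TSS > TTS > exon > intron > intergenic; gene
body without exon annotation counts as intron, and "gene body" excludes
nothing (the promoter window is a separate precedence class, so the
question of whether gene-body overlap includes promoters is resolved by
precedence, not by clipping). Binary occupancy vectors are clustered
hierarchically with Euclidean distance and complete linkage (both
configurable); flat labels are renumbered by first appearance so output
is deterministic.

## Permutation null and categorical tests

The shuffle preserves, per chromosome, (i) the number of peaks, (ii) the
multiset of peak widths and (iii) the peak→chromosome assignment; each
start is uniform on [0, L − w]. Shuffled peaks may overlap one another —
no rejection — which is the simplest null consistent with the three
constraints. The default overlap statistic is the number of *peaks*
overlapping ≥ 1 feature (so the Fisher 2×2 rows sum to the peak count);
the feature-unit statistic (features overlapped, used for the
peaks-vs-promoters regression) is available via `unit="features"`.

The empirical two-sided p-value is the add-one permutation p of the
centred absolute statistic:

    p = (1 + #{ |Xᵢ − X̄| ≥ |X − X̄| }) / (N + 1).

Doubling the smaller of the two tails was rejected: on discrete overlap
counts it is visibly conservative (an atom at p = 1 from ties at the
mode) and fails uniformity under the null, whereas the absolute-deviation
form calibrates cleanly (KS-uniform at N = 200 with peak sets large
enough that the count sd is ~10). The null sd uses ddof = 1; sd = 0
(e.g. features tiling the genome) yields an undefined Z and direction.
The Fisher table is `[[obs, n − obs], [round(null mean), n − round(null
mean)]]`; the paper-style Fisher p is reported alongside the empirical p
and should never be used without it. All randomness derives from one
master seed through named substreams keyed by (seed, dbp, feature-set),
so results do not depend on execution order.

Biotype bias (lncRNA vs mRNA) and reservoir DBP bias use uncorrected
(textbook) χ² on the 2×2 bound/unbound × group table; log₂(obs/exp) is
computed on the bound-lncRNA (resp. bound-reservoir) cell, and fold
change for the reservoir bias is the ratio of bound fractions.
lncRNA over-representation among reservoirs uses the upper-tail
hypergeometric P[X ≥ k].

## Metaprofiles

TSS profiles average a stepwise coverage track over oriented anchors.
Offset 0 is the TSS base on **both** strands: a + strand anchor reads
[tss − f, tss + f), a − strand anchor reads [tss − f + 1, tss + f + 1)
reversed. This asymmetric-looking convention is what makes genome
mirroring (coordinates reversed, strands flipped) an exact symmetry of
the profile, and it is enforced by test to < 1e-9. Windows truncated by
chromosome ends are excluded by default (zero-padding is a config
option); the 95% band is mean ± 1.96·√(var/n) with across-anchor variance
(ddof = 1). Element-centred profiles rescale each element body to a fixed
bin count using exact fractional averages of the step function (via its
cumulative integral), so bodies shorter than the bin count are handled by
the same arithmetic; flanks are binned at a fixed resolution (default
50 bp over 5 kb). Profile-shape clustering uses Euclidean/complete
linkage with the conventional cut height 65 as default; the cut is only
meaningful when profiles share a scale, so an optional unit-max
normalisation is provided (off by default).

## Expression

TPM is count/length rate-normalised to a column sum of exactly 10⁶.
Window quantification is multi-overlap: a read increments every window it
touches, and the window width is the effective length. Expression bins
follow the printed interval semantics: off < 0.001, low = [0.001, 0.137],
medium = (0.137, 3], high > 3 — a TPM of exactly 0.001 is *low*. The
binding–expression correlation reports Pearson on log₁₀(TPM + 0.001)
(pseudocount = the off threshold) and Spearman on raw TPM. Replicates are
averaged per assay before classification.

## Reservoir classification

With defaults min_dbps = 7 and tpm_off = 0.001 (both strict
inequalities): reservoir ⇔ n_dbps > 7 and total-RNA TPM < 0.001. The
binding-count threshold can alternatively be located as the deepest
smoothed-histogram valley between the two largest modes of the n_dbps
distribution (`find_count_threshold(mode="valley")`), falling back to the
fixed value with a warning when the distribution is unimodal. Ghost ⇔
PRO-seq TPM over TSS ± 3 kb < 0.001 (reservoirs only; ghost ∪ zombie
partitions the reservoirs). Conservative ⇔ window TPM < 0.001 in every
total and polyA sample; PRO-seq is not part of the conservative
definition, so conservative and ghost remain independent annotations.

Neighbor classes are evaluated with precedence **multiple_nearby** (≥ 2
other TSSs within 1 kb, any strand) > **bidirectional** (≥ 1
opposite-strand TSS strictly upstream within 1 kb) > **same_strand_nearby**
> **none**. The published categories overlap; their printed percentages
imply mutual exclusivity, and this precedence (documented, configurable in
code) realises it. "Upstream" is measured against the query's
orientation; distances are TSS-to-TSS with strict ≤ 1000 and offset 0 not
counted as upstream. The classifier is verified against an exhaustive
truth table over all ≤ 3-neighbor configurations at offsets ±250/999/
1000/1001 bp.

The 5-gene window statistic orders genes by TSS per chromosome and takes
the mean TPM of the four flanking genes (center excluded), full windows
only; group comparisons (reservoir-centred vs not, SE-centred vs not) use
the two-sided Wilcoxon rank-sum, with SE-overlapping reservoirs removed
from the reservoir group. Super-enhancer overlap flags reservoirs rather
than deleting them. The Pol II flag is occupancy by any DBP on a
configured machinery name list. Chromatin-state association compares mean
nascent TPM with vs without a mark (≥ 1 bp window overlap) by rank-sum.

## Synthetic data: what it emulates, and what it does not

Defaults: 2 chromosomes × 10 Mb, 1,000 genes on a ~20 kb grid (30%
lncRNA, spans 3–8 kb), 40 DBPs × 2 replicates, peak widths
lognormal(μ = 5.7, σ = 0.35) clipped to [100, 1000] bp, replicate jitter
≤ 20 bp with zero dropout, ~150 background peaks per DBP placed away
from promoter windows, a 200-copy SVA-like repeat family (0.8–2 kb)
bound one-peak-per-copy by 3 dedicated DBPs plus three decoy families,
20 super-enhancers centred on highly expressed hosts, and 50 planted
reservoirs (60% ghosts, planted n_dbps 12–30) of which 15 are relocated
2 kb downstream of an expressed host gene so transcription leaks into
their window (these populate the non-conservative reservoir fraction).
Expression follows log₁₀(TPM + 0.001) = 0.1·n_dbps + N(0, 0.5) for
normal genes, with per-sample lognormal replicate noise, reservoirs at
exactly 0 in every RNA sample, and non-reservoirs above the binding
threshold floored at ~0.011 TPM so renormalisation cannot push them into
the off bin. Zombies receive a fixed 50-read nascent dose per PRO-seq
sample; ghosts none. Per-DBP coverage tracks are replicate-peak pileups
(so coverage ≥ 1 under every emitted peak); an H3K4me1-like track ramps
2.0 → 0.2 across each planted-family body 5′→3′, and H3K27ac/H3K27me3
proxies mark expressed/silent promoters. Everything is deterministic by
seed, to the byte.

Deliberate idealisations — and hence what passing tests do *not* show
about real data: peaks are placed, not called from reads (no mappability,
GC, or fragment-length structure); replicate disagreement is a uniform
jitter, not antibody- or depth-dependent; genes sit on a near-regular
grid with no sub-1 kb promoter neighborhoods, so the neighbor-expression
statistics are degenerate on the default bundle (the neighbor classifier
is validated by the truth table instead) — planting bidirectional pairs
was rejected because overlapping windows would share planted peaks and
break the exact occupancy-equals-planted invariant; and with 1,000 genes
the mandatory TPM column sum of 10⁶ inflates every expressed gene to
≫ 1 TPM, so planted reservoirs are far more extreme log-outliers than at
genome scale. For that last reason the binding–expression Pearson
criterion is evaluated on the population that follows the planted
log-linear law (normal genes, n = 950, r ≈ 0.7); across all 1,000 genes
Pearson is dominated by the 50 planted outliers while Spearman stays
strongly positive, and both are reported.

The pipeline's reservoir stage consumes the per-sample TPM tables
(averaged per assay), treating quantification as an upstream input; the
counts→TPM path is implemented and unit-tested, but at the synthetic read
depth a 0.01-TPM gene receives no reads, which is exactly the
below-detection regime the off threshold models.

## Problem sizes and numerical conventions used by the verification suite

The test suite and `scripts/acceptance.py` use: 220 random instances
(2–4 replicates × ≤ 30 peaks) against a union-find consensus oracle;
permutation calibration with 40 peak sets × 5 feature sets (1,200 × 300 bp
peaks, 800 × 1 kb features, 2 × 10 Mb genome, N = 200) chosen so the
integer overlap counts have sd ≈ 10 and tie mass stays small; planted
repeat-family recovery at N = 100; the default 1,000-gene study for
reservoir recovery; and two full pipeline runs for bitwise determinism.
These sizes keep the whole verification under a minute while leaving
every statistical margin wide.

Other numeric conventions: quantile rule nearest-rank (≤); χ² without
continuity correction (matching the hand formula Σ(O−E)²/E); Wilcoxon
rank-sum via the normal approximation (`scipy.stats.ranksums`);
hierarchical-cluster labels renumbered by first appearance; unknown
config keys are hard errors; unknown-chromosome peaks are skipped with a
logged count by default (configurable to fail).

## Limitations

No GC/mappability-matched shuffling (the null is placement-uniform); no
IDR or score-aware merging; no BAM/bigWig I/O (bedGraph and text formats
only); peak-feature annotation is midpoint-based and will not exactly
reproduce annotators that use full-interval logic; UMAP/HDBSCAN-style
embeddings are out of scope; and nothing here supports causal claims
about what reservoir promoters are *for* — the classifier reproduces a
descriptive phenotype.
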