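"""Readers, writers and domain types for the genomic formats the pipeline touches.

All internal coordinates are 0-based, half-open (BED convention).  GTF
input (1-based, closed) is converted on read.  A "promoter window" is the
strand-aware TSS ± flank interval, clipped to chromosome bounds.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

log = logging.getLogger(__name__)

#: Default canonical chromosome set (autosomes + sex chromosomes).
CANONICAL_CHROMS = frozenset(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome name → length map plus a canonical-name subset."""

    chroms: Dict[str, int]
    canonical: FrozenSet[str] = field(default_factory=lambda: CANONICAL_CHROMS)

    def __post_init__(self):
        for name, length in self.chroms.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(
            self, "canonical", frozenset(self.canonical) & set(self.chroms)
        )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def length(self, chrom: str) -> int:
        return self.chroms[chrom]

    @property
    def names(self) -> List[str]:
        return list(self.chroms)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with optional strand ('+', '-', '.')."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """One ChIP-seq peak from one replicate of one DNA-binding protein."""

    interval: GenomicInterval
    dbp: str
    replicate: int
    score: Optional[float] = None

    def __post_init__(self):
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneModel:
    """Gene span with biotype and TSS; exons optional (used by the feature annotator)."""

    gene_id: str
    biotype: str  # "mRNA" or "lncRNA"
    span: GenomicInterval
    effective_length: Optional[int] = None
    exons: Tuple[GenomicInterval, ...] = ()

    def __post_init__(self):
        if self.biotype not in ("mRNA", "lncRNA"):
            raise ValueError(f"unsupported biotype {self.biotype!r}")
        if self.span.strand not in ("+", "-"):
            raise ValueError("gene span must be stranded")
        if self.effective_length is None:
            object.__setattr__(self, "effective_length", self.span.width)
        if self.effective_length <= 0:
            raise ValueError("effective length must be positive")

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        # 0-based coordinate of the 5' end: last covered base on '-' strand
        return self.span.start if self.strand == "+" else self.span.end - 1


@dataclass(frozen=True)
class PromoterWindow:
    """TSS ± flank window, clipped to the chromosome; carries strand for orientation."""

    gene_id: str
    interval: GenomicInterval
    flank: int
    tss: int
    strand: str

    def __post_init__(self):
        if self.interval.width > 2 * self.flank:
            raise ValueError("promoter window wider than 2*flank")
        if not (self.interval.start <= self.tss < self.interval.end):
            raise ValueError("promoter window must contain its TSS")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class RepeatElement:
    """One RepeatMasker element with its repeat name, family and class."""

    interval: GenomicInterval
    name: str
    family: str
    repeat_class: str

    def __post_init__(self):
        if not self.family or not self.repeat_class:
            raise ValueError("repeat family and class must be non-empty")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_genome(path, canonical: Optional[Iterable[str]] = None) -> GenomeAssembly:
    """Parse a two-column chrom.sizes file into a GenomeAssembly.

    Duplicate names, non-positive lengths and empty files are rejected.
    """
    chroms: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'name<TAB>length'")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
            if name in chroms:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length for {name!r}")
            chroms[name] = length
    if not chroms:
        raise FormatError(f"{path}: empty chrom.sizes file")
    return GenomeAssembly(
        chroms, frozenset(canonical) if canonical is not None else CANONICAL_CHROMS
    )


def read_peaks(
    path,
    dbp: str,
    replicate: int,
    genome: GenomeAssembly,
    on_unknown_chrom: str = "skip",
) -> List[Peak]:
    """Read a broadPeak / BED3+ file into Peaks validated against the genome.

    broadPeak column 7 (signalValue) is stored as the peak score when
    present.  Intervals on unknown chromosomes or exceeding the chromosome
    length are skipped with a logged count (``on_unknown_chrom='skip'``) or
    raise (``'error'``).  Input order is preserved.
    """
    if on_unknown_chrom not in ("skip", "error"):
        raise ValueError("on_unknown_chrom must be 'skip' or 'error'")
    peaks: List[Peak] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            bad = chrom not in genome or end > genome.length(chrom) or start < 0
            if bad:
                if on_unknown_chrom == "error":
                    raise FormatError(
                        f"{path}:{lineno}: interval {chrom}:{start}-{end} "
                        "outside assembly"
                    )
                n_skipped += 1
                continue
            score = None
            if len(fields) >= 7:
                try:
                    score = float(fields[6])
                except ValueError:
                    score = None
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), dbp, replicate, score)
            )
    if n_skipped:
        log.warning("%s: skipped %d peaks outside the assembly", path, n_skipped)
    return peaks


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')

_BIOTYPE_MAP = {
    "protein_coding": "mRNA",
    "mRNA": "mRNA",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
}


def read_gtf_genes(path, genome: Optional[GenomeAssembly] = None) -> List[GeneModel]:
    """Parse gene (and optional exon) records from a GENCODE-like GTF.

    Only mRNA (protein_coding) and lncRNA biotypes are retained.  GTF
    1-based closed coordinates are converted to 0-based half-open.
    """
    genes: Dict[str, dict] = {}
    exons: Dict[str, List[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            gene_id = attr.get("gene_id")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            start, end = int(start1) - 1, int(end1)
            if feature == "exon":
                exons.setdefault(gene_id, []).append(
                    GenomicInterval(chrom, start, end, strand)
                )
                continue
            raw_bt = attr.get("gene_type", attr.get("gene_biotype", ""))
            biotype = _BIOTYPE_MAP.get(raw_bt)
            if biotype is None:
                continue  # out-of-scope biotypes are dropped
            if genome is not None and chrom not in genome:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            genes[gene_id] = dict(
                gene_id=gene_id,
                biotype=biotype,
                span=GenomicInterval(chrom, start, end, strand),
            )
    return [
        GeneModel(exons=tuple(exons.get(gid, ())), **info)
        for gid, info in genes.items()
    ]


def read_repeats(path) -> List[RepeatElement]:
    """Read a UCSC rmsk-style table (header with genoName/genoStart/... columns)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = ["genoName", "genoStart", "genoEnd", "repName", "repClass", "repFamily"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing rmsk columns {missing}")
    elements: List[RepeatElement] = []
    for i, row in enumerate(df.itertuples(index=False), 2):  # 2 = first data line
        strand = getattr(row, "strand", ".")
        if strand not in ("+", "-", "."):
            strand = "."
        try:
            iv = GenomicInterval(
                str(row.genoName), int(row.genoStart), int(row.genoEnd), strand
            )
            elements.append(
                RepeatElement(iv, str(row.repName), str(row.repFamily), str(row.repClass))
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}:{i}: malformed rmsk row ({exc})") from exc
    return elements


def extract_promoters(
    genes: Sequence[GeneModel],
    genome: GenomeAssembly,
    flank: int = 3000,
) -> List[PromoterWindow]:
    """Strand-aware TSS ± flank windows, clipped to [0, chromosome length)."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    windows = []
    for gene in genes:
        if gene.chrom not in genome:
            raise ValueError(f"gene {gene.gene_id} on unknown chromosome {gene.chrom}")
        length = genome.length(gene.chrom)
        tss = gene.tss
        start = max(0, tss - flank)
        end = min(length, tss + flank)
        windows.append(
            PromoterWindow(
                gene_id=gene.gene_id,
                interval=GenomicInterval(gene.chrom, start, end),
                flank=flank,
                tss=tss,
                strand=gene.strand,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_bed(intervals: Iterable[GenomicInterval], path, names: Optional[Iterable[str]] = None):
    """Write intervals as BED3 (or BED6 when names given and any strand set)."""
    intervals = list(intervals)
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is not None or iv.strand != ".":
                name = names[i] if names is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path) -> List[GenomicInterval]:
    """Read BED3/BED6 into GenomicIntervals (strand from column 6 when present)."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out
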