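"""Per-gene mitoribosome footprint occupancy and translation efficiency.

Footprint reads are assigned to mitochondrial genes by their 5'-end
position on the sense strand.  Reads starting within the first 15 nt of
a CDS or its last 45 nt are excluded (ribosomes paused at initiation or
termination), as are reads landing in the ATP8/ATP6 and ND4L/ND4
overlapping CDS regions (ambiguous assignment).  Counts are normalised
to reads per million (RPM) of positive-sense nuclear-encoded mRNA reads
in the same library — an externally supplied integer, since nuclear
alignment is upstream of this package.  Occupancy compares knock-out to
parental footprint RPM per gene, as a percentage.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import Strand

logger = logging.getLogger(__name__)

DEFAULT_START_WINDOW = 15
DEFAULT_STOP_WINDOW = 45


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's CDS in 1-based inclusive reference coordinates."""

    gene: str
    category: str  # mRNA, rRNA or tRNA
    strand: Strand
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.cds_start > self.cds_end:
            raise ValueError(
                f"{self.gene}: cds_start {self.cds_start} > cds_end "
                f"{self.cds_end}"
            )

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    def offset_of(self, pos: int) -> int | None:
        """Transcript-sense offset of reference position within the CDS."""
        if not (self.cds_start <= pos <= self.cds_end):
            return None
        if self.strand == Strand.plus:
            return pos - self.cds_start
        return self.cds_end - pos


@dataclass(frozen=True)
class OverlapInterval:
    """Reference interval shared by two genes; ambiguous for assignment."""

    gene_a: str
    gene_b: str
    start: int
    end: int


@dataclass
class MtAnnotation:
    genes: tuple[GeneAnnotation, ...]
    overlaps: tuple[OverlapInterval, ...] = ()

    def __post_init__(self) -> None:
        by_name = {g.gene: g for g in self.genes}
        for ov in self.overlaps:
            for name in (ov.gene_a, ov.gene_b):
                g = by_name.get(name)
                if g is None:
                    raise ValueError(f"overlap names unknown gene {name}")
                if not (g.cds_start <= ov.start and ov.end <= g.cds_end):
                    raise ValueError(
                        f"overlap [{ov.start}, {ov.end}] not inside CDS of "
                        f"{name}"
                    )

    def mrna_genes(self) -> tuple[GeneAnnotation, ...]:
        return tuple(g for g in self.genes if g.category == "mRNA")

    def gene(self, name: str) -> GeneAnnotation:
        for g in self.genes:
            if g.gene == name:
                return g
        raise KeyError(name)


def load_annotation(bed_path, overlaps_path=None) -> MtAnnotation:
    """Load a BED-like gene table (and optional overlap intervals).

    On disk BED coordinates are 0-based half-open; they are converted
    to 1-based inclusive on load.  Columns: chrom, start, end, name,
    category, strand.  The overlap file uses name = "geneA|geneB".
    """
    def read_bed(path):
        return pd.read_csv(
            path, sep="\t", comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
        )

    genes = []
    for row in read_bed(bed_path).itertuples():
        genes.append(GeneAnnotation(
            gene=row.name, category=str(row.score),
            strand=Strand(row.strand),
            cds_start=int(row.start) + 1, cds_end=int(row.end),
        ))
    overlaps = []
    if overlaps_path is not None:
        for row in read_bed(overlaps_path).itertuples():
            a, b = str(row.name).split("|")
            overlaps.append(OverlapInterval(
                gene_a=a, gene_b=b,
                start=int(row.start) + 1, end=int(row.end),
            ))
    return MtAnnotation(genes=tuple(genes), overlaps=tuple(overlaps))


def human_mt_mrna_annotation() -> MtAnnotation:
    """The 13 human mtDNA protein-coding genes with both overlap pairs."""
    data = importlib.resources.files("mitomethyl.data")
    with importlib.resources.as_file(data / "human_mt_mrna.bed") as bed, \
            importlib.resources.as_file(
                data / "human_mt_overlaps.bed") as ov:
        return load_annotation(bed, ov)


@dataclass(frozen=True)
class FootprintRead:
    """One ribosome-protected fragment (5' position, length, strand)."""

    five_prime_pos: int
    length: int
    strand: Strand = Strand.plus

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("read length must be positive")


def filter_footprints(
    reads: Sequence[FootprintRead],
    annotation: MtAnnotation,
    start_window: int = DEFAULT_START_WINDOW,
    stop_window: int = DEFAULT_STOP_WINDOW,
) -> tuple[list[tuple[FootprintRead, str]], dict[str, int]]:
    """Assign footprints to genes and drop initiation/termination/ambiguous reads.

    A read is assigned by its 5'-end position to the sense-strand mRNA
    CDS containing it, then dropped if that offset lies in the first
    ``start_window`` CDS positions (paused initiating ribosomes), in the
    last ``stop_window`` positions (terminating ribosomes), or inside an
    annotated overlap interval (ambiguous between both genes).  Reads on
    no annotated mRNA count as intergenic.  Each read is counted at most
    once.

    Returns the kept ``(read, gene)`` assignments and per-rule drop
    counts (keys: start_window, stop_window, overlap, intergenic).
    """
    drops = {"start_window": 0, "stop_window": 0, "overlap": 0,
             "intergenic": 0}
    kept: list[tuple[FootprintRead, str]] = []
    mrnas = annotation.mrna_genes()
    for read in reads:
        pos = read.five_prime_pos
        in_overlap = any(ov.start <= pos <= ov.end
                         for ov in annotation.overlaps)
        if in_overlap:
            drops["overlap"] += 1
            continue
        hit = None
        for g in mrnas:
            if g.strand != read.strand:
                continue
            o = g.offset_of(pos)
            if o is not None:
                hit = (g, o)
                break
        if hit is None:
            drops["intergenic"] += 1
            continue
        g, o = hit
        if o <= start_window - 1:
            drops["start_window"] += 1
            continue
        if o >= g.cds_length - stop_window:
            drops["stop_window"] += 1
            continue
        kept.append((read, g.gene))
    return kept, drops


def count_footprints(
    kept: Iterable[tuple[FootprintRead, str]],
    annotation: MtAnnotation,
) -> dict[str, int]:
    """Per-gene footprint counts over all annotated mRNAs (zeros included)."""
    counts = {g.gene: 0 for g in annotation.mrna_genes()}
    for _, gene in kept:
        counts[gene] += 1
    return counts


def rpm_normalize(count: int, nuclear_mrna_reads: int) -> float:
    """Reads per million of the library's positive-sense nuclear-mRNA reads."""
    if nuclear_mrna_reads <= 0:
        raise ValueError(
            f"nuclear-mRNA normaliser must be positive, got "
            f"{nuclear_mrna_reads}"
        )
    return count / nuclear_mrna_reads * 1e6


def translation_efficiency(ribo_rpm: float, rna_rpm: float) -> float:
    """Footprint RPM over RNA-seq RPM; NaN where RNA RPM is zero."""
    if rna_rpm > 0:
        return ribo_rpm / rna_rpm
    return math.nan


def expression_table(
    gene_counts: Mapping[str, int],
    nuclear_mrna_reads: int,
    rna_rpm: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble per-gene counts into an expression table with RPM and TE."""
    rows = []
    for gene, count in gene_counts.items():
        ribo_rpm = rpm_normalize(count, nuclear_mrna_reads)
        g_rna = rna_rpm.get(gene, math.nan) if rna_rpm else math.nan
        te = (translation_efficiency(ribo_rpm, g_rna)
              if np.isfinite(g_rna) else math.nan)
        rows.append({"gene": gene, "ribo_count": count, "ribo_rpm": ribo_rpm,
                     "rna_rpm": g_rna, "te": te})
    return pd.DataFrame(rows)


@dataclass
class OccupancySummary:
    """Knock-out / parental footprint density per gene, in percent."""

    per_gene_occupancy: dict[str, float]
    mean: float
    sd: float
    min: float
    median: float
    max: float
    excluded_genes: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.per_gene_occupancy),
             "occupancy_percent": list(self.per_gene_occupancy.values())}
        )


def occupancy(
    ko: pd.DataFrame, parental: pd.DataFrame,
) -> OccupancySummary:
    """Per-gene knock-out occupancy as a percentage of parental.

    Both tables need columns ``gene`` and ``ribo_rpm``.  Genes absent
    from either table or with zero parental RPM are excluded (listed in
    the summary).  The summary statistics (mean, sample SD, min, median,
    max) are computed over the included genes only.
    """
    ko_rpm = dict(zip(ko["gene"], ko["ribo_rpm"]))
    par_rpm = dict(zip(parental["gene"], parental["ribo_rpm"]))
    shared = [g for g in par_rpm if g in ko_rpm]
    if not shared:
        raise ValueError("no shared genes between knock-out and parental "
                         "tables")
    per_gene: dict[str, float] = {}
    excluded: list[str] = []
    for g in shared:
        if par_rpm[g] > 0:
            per_gene[g] = 100.0 * ko_rpm[g] / par_rpm[g]
        else:
            excluded.append(g)
    if excluded:
        logger.info("excluded genes with zero parental RPM: %s", excluded)
    if not per_gene:
        raise ValueError("every shared gene has zero parental RPM")
    vals = np.array(list(per_gene.values()))
    return OccupancySummary(
        per_gene_occupancy=per_gene,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        min=float(vals.min()),
        median=float(np.median(vals)),
        max=float(vals.max()),
        excluded_genes=tuple(excluded),
    )
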