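"""Genomic intervals, gene models, region classification and signed distances.

All coordinates are 1-based and inclusive at both ends (VCF convention).
"Upstream" is always defined in gene orientation: for a minus-strand gene
such as ROBO1 the upstream direction points toward *larger* genomic
coordinates, and signed distances to the 5' anchor are negative on the
upstream side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence


class DifferentChromosomeError(ValueError):
    """Raised when a signed distance is requested across chromosomes."""


@dataclass(frozen=True)
class GenomeInterval:
    """A closed genomic interval [start, end], 1-based inclusive."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def width_mb(self) -> int:
        """Interval width rounded to the nearest megabase."""
        return int(round(self.length / 1e6))

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


class RegionClass(Enum):
    """Gene-relative region class of a position.

    ``UPSTREAM`` is the fine class; summary tables that follow the
    convention of labelling upstream variants "Intergenic" can use
    :attr:`display` instead.
    """

    EXONIC = "exonic"
    FIVE_UTR = "5UTR"
    THREE_UTR = "3UTR"
    INTRONIC = "intronic"
    UPSTREAM = "upstream"
    INTERGENIC = "intergenic"

    @property
    def display(self) -> str:
        if self is RegionClass.UPSTREAM:
            return "Intergenic"
        return self.value.capitalize() if self.value.islower() else self.value


@dataclass
class GeneModel:
    """Strand-aware single-transcript gene model.

    The 5' ``anchor`` is the transcription start: the maximum exon end for
    a minus-strand gene, the minimum exon start for a plus-strand gene.
    ``coding`` intervals (may be empty for a non-coding model) drive the
    exonic/UTR split.
    """

    name: str
    chrom: str
    strand: str
    exons: Sequence[GenomeInterval]
    coding: Sequence[GenomeInterval] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end >= b.start:
                raise ValueError(f"overlapping exons {a} and {b}")

    @property
    def anchor(self) -> int:
        if self.strand == "-":
            return max(e.end for e in self.exons)
        return min(e.start for e in self.exons)

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
        )


def signed_distance(pos: int, gene: GeneModel, chrom: str | None = None) -> int:
    """Signed base offset of ``pos`` from the gene's 5' anchor.

    Positive values lie inside or downstream of the 5' anchor in gene
    orientation; negative values lie upstream.  For a minus-strand gene the
    distance is ``anchor - pos``; for plus strand, ``pos - anchor``.
    """
    if chrom is not None and chrom != gene.chrom:
        raise DifferentChromosomeError(
            f"position on {chrom}, gene {gene.name} on {gene.chrom}"
        )
    if gene.strand == "-":
        return gene.anchor - pos
    return pos - gene.anchor


def classify_region(
    pos: int,
    gene: GeneModel,
    upstream_window: int = 1_000_000,
    chrom: str | None = None,
) -> RegionClass:
    """Classify a position relative to a gene model.

    Precedence: exonic (split into coding/5'UTR/3'UTR when coding intervals
    are annotated) > intronic > upstream (within ``upstream_window`` of the
    5' anchor, in gene orientation) > intergenic.  A position on another
    chromosome is intergenic, with a warning.
    """
    if chrom is not None and chrom != gene.chrom:
        warnings.warn(
            f"position {chrom}:{pos} not on gene chromosome {gene.chrom}; "
            "classified intergenic",
            stacklevel=2,
        )
        return RegionClass.INTERGENIC

    in_exon = any(e.start <= pos <= e.end for e in gene.exons)
    if in_exon:
        if not gene.coding:
            return RegionClass.EXONIC
        if any(c.start <= pos <= c.end for c in gene.coding):
            return RegionClass.EXONIC
        cds_lo = min(c.start for c in gene.coding)
        cds_hi = max(c.end for c in gene.coding)
        if gene.strand == "-":
            return RegionClass.FIVE_UTR if pos > cds_hi else RegionClass.THREE_UTR
        return RegionClass.FIVE_UTR if pos < cds_lo else RegionClass.THREE_UTR

    span = gene.span
    if span.start <= pos <= span.end:
        return RegionClass.INTRONIC

    d = signed_distance(pos, gene)
    if d < 0 and -d <= upstream_window:
        return RegionClass.UPSTREAM
    return RegionClass.INTERGENIC


def upstream_window(
    gene: GeneModel, width: int, chrom_length: int | None = None
) -> GenomeInterval:
    """The interval of exactly ``width`` bases directly 5' of the gene.

    Begins one base beyond the 5' anchor in gene orientation; clipped at
    chromosome bounds (position 1, and ``chrom_length`` if given).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    a = gene.anchor
    if gene.strand == "-":
        start, end = a + 1, a + width
        if chrom_length is not None:
            end = min(end, chrom_length)
    else:
        start, end = max(1, a - width), a - 1
    return GenomeInterval(gene.chrom, start, end)


def read_gene_model_bed12(path: str) -> GeneModel:
    """Read a single-transcript gene model from a BED12 line.

    BED is 0-based half-open; coordinates are converted to the package's
    1-based inclusive convention.  thickStart/thickEnd define the coding
    region (equal values mean non-coding).
    """
    with open(path) as fh:
        line = next(
            l for l in fh if l.strip() and not l.startswith(("#", "track", "browser"))
        )
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError(f"expected 12 BED columns, got {len(f)}")
    chrom, chrom_start = f[0], int(f[1])
    name, strand = f[3], f[5]
    thick_start, thick_end = int(f[6]), int(f[7])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
    exons = [
        GenomeInterval(chrom, chrom_start + off + 1, chrom_start + off + size)
        for off, size in zip(offsets, sizes)
    ]
    coding: list[GenomeInterval] = []
    if thick_end > thick_start:
        for e in exons:
            lo = max(e.start, thick_start + 1)
            hi = min(e.end, thick_end)
            if lo <= hi:
                coding.append(GenomeInterval(chrom, lo, hi))
    return GeneModel(name=name, chrom=chrom, strand=strand, exons=exons, coding=coding)


# -- Published fixture coordinates -------------------------------------------

#: The dyslexia susceptibility haplotype interval on chromosome 3
#: (microsatellite markers D3S3039..D3S3045), closed at both printed ends.
HAPLOTYPE_INTERVAL = GenomeInterval("chr3", 73_842_243, 106_990_161)

#: Published intronic-variant row used to recover the ROBO1 5' anchor:
#: position 79667838 lies +149,221 bases from the 5' end of the brain-specific
#: transcript, so the anchor is derivable as pos + distance on the minus strand.
_INTRONIC_VARIANT_POS = 79_667_838
_INTRONIC_VARIANT_DISTANCE = 149_221


def robo1_anchor() -> int:
    """ROBO1 5' anchor derived from the published position/distance pair."""
    return _INTRONIC_VARIANT_POS + _INTRONIC_VARIANT_DISTANCE


def robo1_model() -> GeneModel:
    """A representative ROBO1 gene model (minus strand, chr3).

    The 5' anchor is the derived transcription start of the long
    brain-specific transcript; exon/coding coordinates other than the anchor
    are synthetic placeholders shaped like the real gene (a 5' non-coding
    first exon followed by coding exons), sufficient to drive region
    classification in simulations.
    """
    anchor = robo1_anchor()
    chrom = "chr3"
    exons = [
        GenomeInterval(chrom, 78_650_000, 78_652_000),
        GenomeInterval(chrom, 79_000_000, 79_000_500),
        GenomeInterval(chrom, 79_743_000, 79_743_500),
        GenomeInterval(chrom, anchor - 559, anchor),  # 5' non-coding exon
    ]
    coding = [
        GenomeInterval(chrom, 78_650_200, 78_652_000),
        GenomeInterval(chrom, 79_000_000, 79_000_500),
        GenomeInterval(chrom, 79_743_000, 79_743_200),
    ]
    return GeneModel(name="ROBO1", chrom=chrom, strand="-", exons=exons, coding=coding)
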