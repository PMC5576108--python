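"""Genomic annotation containers: intervals, TE instances and gene models.

All coordinates are 0-based half-open (BED convention). GTF-style inputs
must be converted on read; a single internal convention keeps the interval
arithmetic bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

TE_CLASSES = ("SINE", "LINE", "LTR", "DNA")
COMPARTMENTS = ("CDS", "UTR", "Intron", "Intergenic")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class TEInstance:
    """One TE copy in the genome, carrying the class/family/subfamily hierarchy."""

    te_id: str
    interval: GenomicInterval
    te_class: str
    family: str
    subfamily: str
    compartment: str | None = None

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}; expected {TE_CLASSES}")

    def with_compartment(self, compartment: str) -> "TEInstance":
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}")
        return replace(self, compartment=compartment)


@dataclass(frozen=True)
class GeneModel:
    """A gene with merged exon structure (no isoform resolution).

    ``cds_exons`` and ``utr_exons`` are (start, end) tuples in genomic
    coordinates; introns are the gaps of the gene span not covered by any
    exon. The TSS is the 5' end of the span on the gene's strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)
    utr_exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError("invalid gene span")
        exons = sorted(self.cds_exons + self.utr_exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def exons(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(self.cds_exons + self.utr_exons))

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        exons = self.exons
        if not exons:
            return ((self.start, self.end),)
        introns = []
        if self.start < exons[0][0]:
            introns.append((self.start, exons[0][0]))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 < s2:
                introns.append((e1, s2))
        if exons[-1][1] < self.end:
            introns.append((exons[-1][1], self.end))
        return tuple(introns)
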