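"""Assign TE instances to genomic compartments by overlap fraction + priority.

A TE is assigned to the highest-priority feature type (CDS exon > UTR exon >
intron; intergenic otherwise) with which some single feature interval covers
at least ``min_fraction`` of the TE's length. The fraction is measured
relative to the TE, mirroring ``bedtools intersect -f`` semantics, and
overlap is computed strand-blind.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import COMPARTMENTS, GeneModel, GenomicInterval, TEInstance

logger = logging.getLogger(__name__)

#: genic feature types in decreasing priority
PRIORITY = ("CDS", "UTR", "Intron")


def overlap_fraction(te: GenomicInterval, feature: GenomicInterval) -> float:
    """Fraction of the TE covered by the feature (0 if on different chroms)."""
    if len(te) == 0:
        raise ValueError("zero-length TE interval")
    if te.chrom != feature.chrom:
        return 0.0
    overlap = min(te.end, feature.end) - max(te.start, feature.start)
    return max(overlap, 0) / len(te)


@dataclass
class CompartmentAnnotation:
    """Per-chromosome interval indexes for CDS exons, UTR exons and introns."""

    trees: dict[str, dict[str, IntervalTree]] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls,
        cds: Iterable[tuple[str, int, int]],
        utr: Iterable[tuple[str, int, int]],
        intron: Iterable[tuple[str, int, int]],
    ) -> "CompartmentAnnotation":
        ann = cls()
        for kind, intervals in (("CDS", cds), ("UTR", utr), ("Intron", intron)):
            for chrom, start, end in intervals:
                if start >= end:
                    continue
                ann.trees.setdefault(chrom, {k: IntervalTree() for k in PRIORITY})
                ann.trees[chrom][kind].addi(start, end)
        return ann

    @classmethod
    def from_genes(cls, genes: Sequence[GeneModel]) -> "CompartmentAnnotation":
        def pull(attr):
            for g in genes:
                for s, e in getattr(g, attr):
                    yield (g.chrom, s, e)

        return cls.from_intervals(pull("cds_exons"), pull("utr_exons"), pull("introns"))

    def best_fraction(self, te: GenomicInterval, kind: str) -> float:
        """Largest single-feature overlap fraction of the TE for one feature type."""
        chrom_trees = self.trees.get(te.chrom)
        if chrom_trees is None:
            return 0.0
        best = 0.0
        for iv in chrom_trees[kind].overlap(te.start, te.end):
            frac = (min(te.end, iv.end) - max(te.start, iv.begin)) / len(te)
            if frac > best:
                best = frac
        return best


def assign_compartment(
    te: GenomicInterval,
    annotation: CompartmentAnnotation,
    min_fraction: float = 0.5,
) -> str:
    """Compartment label for a single interval under the priority rule."""
    for kind in PRIORITY:
        if annotation.best_fraction(te, kind) >= min_fraction:
            return kind
    return "Intergenic"


def assign_compartments(
    tes: Sequence[TEInstance],
    annotation: CompartmentAnnotation,
    min_fraction: float = 0.5,
) -> list[TEInstance]:
    """Assign every TE exactly one compartment; order-independent.

    TEs on chromosomes absent from the annotation become Intergenic with a
    logged warning.
    """
    missing: set[str] = set()
    out = []
    for te in tes:
        if te.interval.chrom not in annotation.trees:
            missing.add(te.interval.chrom)
        out.append(te.with_compartment(assign_compartment(te.interval, annotation, min_fraction)))
    for chrom in sorted(missing):
        logger.warning("chromosome %s absent from annotation; TEs set to Intergenic", chrom)
    return out


def compartment_summary(tes: Sequence[TEInstance]) -> pd.DataFrame:
    """Per-class compartment proportions plus the all-TE marginal.

    Rows are TE classes (classes with no instances are omitted and logged)
    plus an ``all`` row; columns are compartments; each row sums to 1.
    """
    if any(te.compartment is None for te in tes):
        raise ValueError("all TEs must be assigned before summarizing")
    df = pd.DataFrame(
        {"te_class": [t.te_class for t in tes], "compartment": [t.compartment for t in tes]}
    )
    counts = (
        df.groupby(["te_class", "compartment"], sort=True).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=list(COMPARTMENTS), fill_value=0)
    present = set(counts.index)
    from .annotation import TE_CLASSES

    for cls_ in TE_CLASSES:
        if cls_ not in present:
            logger.info("no %s instances supplied; row omitted from summary", cls_)
    counts.loc["all"] = counts.sum(axis=0)
    props = counts.div(counts.sum(axis=1), axis=0)
    props.index.name = "te_class"
    return props
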