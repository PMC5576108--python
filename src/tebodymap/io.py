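"""Plain-text readers/writers for the pipeline's tables.

All coordinates on disk follow BED conventions (0-based half-open);
matrices are TSV with features as rows and samples as columns.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .annotation import GeneModel, GenomicInterval, TEInstance
from .design import SampleDesign, design_from_metadata, metadata_frame
from .expression import ExpressionMatrix


# -- matrices --------------------------------------------------------------

def write_matrix(matrix: ExpressionMatrix | pd.DataFrame, path: str | Path) -> None:
    df = matrix.rpkm if isinstance(matrix, ExpressionMatrix) else matrix
    df.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6g")

def read_matrix(path: str | Path, design: SampleDesign) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    return ExpressionMatrix(df, design)


# -- sample metadata -------------------------------------------------------

def write_metadata(design: SampleDesign, path: str | Path) -> None:
    metadata_frame(design).to_csv(path, sep="\t")

def read_metadata(path: str | Path) -> SampleDesign:
    return design_from_metadata(pd.read_csv(path, sep="\t"))


# -- TE annotation ---------------------------------------------------------

def write_te_annotation(tes: list[TEInstance], bed_path: str | Path,
                        table_path: str | Path) -> None:
    """BED6 of TE intervals plus a TSV with the class hierarchy (+ compartment)."""
    with open(bed_path, "w") as fh:
        for t in tes:
            iv = t.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.te_id}\t0\t{iv.strand}\n")
    rows = [
        {"te_id": t.te_id, "chrom": t.interval.chrom, "start": t.interval.start,
         "end": t.interval.end, "strand": t.interval.strand, "te_class": t.te_class,
         "family": t.family, "subfamily": t.subfamily,
         "compartment": t.compartment or ""}
        for t in tes
    ]
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)

def read_te_annotation(table_path: str | Path) -> list[TEInstance]:
    df = pd.read_csv(table_path, sep="\t", keep_default_na=False)
    return [
        TEInstance(r.te_id, GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand),
                   r.te_class, r.family, r.subfamily,
                   r.compartment or None)
        for r in df.itertuples(index=False)
    ]


# -- gene annotation -------------------------------------------------------

def write_gene_annotation(genes: list[GeneModel], table_path: str | Path,
                          tss_bed_path: str | Path | None = None) -> None:
    """Exon-level TSV (gene_id, chrom, start, end, strand, feature) + TSS BED6."""
    rows = []
    for g in genes:
        rows.append({"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start,
                     "end": g.end, "strand": g.strand, "feature": "gene"})
        for s, e in g.cds_exons:
            rows.append({"gene_id": g.gene_id, "chrom": g.chrom, "start": s,
                         "end": e, "strand": g.strand, "feature": "CDS"})
        for s, e in g.utr_exons:
            rows.append({"gene_id": g.gene_id, "chrom": g.chrom, "start": s,
                         "end": e, "strand": g.strand, "feature": "UTR"})
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)
    if tss_bed_path is not None:
        with open(tss_bed_path, "w") as fh:
            for g in genes:
                fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t0\t{g.strand}\n")

def read_gene_annotation(table_path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(table_path, sep="\t")
    genes = []
    for gid, sub in df.groupby("gene_id", sort=False):
        span = sub[sub["feature"] == "gene"].iloc[0]
        cds = tuple(sorted((int(r.start), int(r.end))
                           for r in sub[sub["feature"] == "CDS"].itertuples()))
        utr = tuple(sorted((int(r.start), int(r.end))
                           for r in sub[sub["feature"] == "UTR"].itertuples()))
        genes.append(GeneModel(gid, span.chrom, int(span.start), int(span.end),
                               span.strand, cds, utr))
    return genes


# -- config ---------------------------------------------------------------

def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj

def write_config_yaml(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(dataclasses.asdict(config)), fh, sort_keys=False)
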