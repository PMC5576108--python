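"""End-to-end orchestration: simulate -> compartments -> classes ->
differential -> variance -> gene-TE links, with one summary artifact.

Every stage writes its table under the output directory; the summary YAML
collects the headline counts so a run is reproducible and self-describing.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from .compartments import CompartmentAnnotation, assign_compartments, compartment_summary
from .design import enumerate_groups, enumerate_samples, pattern_alphabet
from .differential import organ_enriched, pattern_counts, sex_dependent, temporal_pattern
from .expression import classify_expression, replicate_reproducibility
from .links import (build_pair_sets, distance_independence, link_tes_to_genes,
                    pcc_distribution_analysis, significance_cutoff)
from .simulate import SimulationConfig, default_config, simulate_dataset
from .variance import cluster_samples, dendrogram_newick, pvca

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "tebodymap_run"
    simulation: SimulationConfig | None = None
    expressed_rpkm: float = 1.0
    fc_threshold: float = 2.0
    alpha: float = 0.05
    min_overlap_fraction: float = 0.5
    pvca_threshold: float = 0.6
    cutoff_percentile: float = 95.0
    dip_boot: int = 500

    def __post_init__(self) -> None:
        for name in ("expressed_rpkm", "fc_threshold", "alpha",
                     "min_overlap_fraction", "pvca_threshold", "cutoff_percentile"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def run_all(config: RunConfig) -> dict:
    """Run every stage in dependency order; returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.simulation or default_config(config.seed)
    if sim_cfg.seed != config.seed:
        sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)

    logger.info("simulating dataset (seed=%d)", config.seed)
    ds = simulate_dataset(sim_cfg)
    design = ds.design
    tio.write_metadata(design, out / "samples.tsv")
    tio.write_gene_annotation(ds.annotation.genes, out / "genes.tsv", out / "tss.bed")
    tio.write_matrix(ds.subfamily_matrix, out / "subfamily_rpkm.tsv")
    tio.write_matrix(ds.instance_matrix, out / "instance_rpkm.tsv")
    tio.write_matrix(ds.gene_matrix, out / "gene_rpkm.tsv")
    ds.truth.subfamily_roles.to_csv(out / "truth_subfamilies.tsv", sep="\t", index=False)
    ds.truth.pair_table.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
    tio.write_config_yaml(sim_cfg, out / "simulation_config.yaml")

    logger.info("assigning genomic compartments")
    ann = CompartmentAnnotation.from_genes(ds.annotation.genes)
    tes = assign_compartments(ds.annotation.tes, ann, config.min_overlap_fraction)
    tio.write_te_annotation(tes, out / "tes.bed", out / "tes.tsv")
    comp = compartment_summary(tes)
    comp.to_csv(out / "compartment_summary.tsv", sep="\t")

    logger.info("classifying expression")
    classes = classify_expression(ds.subfamily_matrix, config.expressed_rpkm)
    classes.frame().to_csv(out / "expression_classes.tsv", sep="\t", index=False)
    repro = replicate_reproducibility(ds.subfamily_matrix)
    repro.drop(columns="pcc_values").to_csv(out / "replicate_pcc.tsv", sep="\t", index=False)

    logger.info("differential calling")
    enriched = {
        stage: organ_enriched(ds.subfamily_matrix, stage,
                              fc_threshold=config.fc_threshold, alpha=config.alpha)
        for stage in design.stages
    }
    enr_rows = [
        {"stage": stage, "organ": organ, "subfamily": sf}
        for stage, per_organ in enriched.items()
        for organ, subs in per_organ.items()
        for sf in sorted(subs)
    ]
    pd.DataFrame(enr_rows, columns=["stage", "organ", "subfamily"]).to_csv(
        out / "organ_enriched.tsv", sep="\t", index=False)

    patterns = pd.concat(
        [temporal_pattern(ds.subfamily_matrix, organ,
                          fc_threshold=config.fc_threshold, alpha=config.alpha)
         for organ in design.organs], ignore_index=True)
    patterns.to_csv(out / "temporal_patterns.tsv", sep="\t", index=False)
    sexdiff = sex_dependent(ds.subfamily_matrix,
                            fc_threshold=config.fc_threshold, alpha=config.alpha)
    sexdiff[sexdiff["call"] != "none"].to_csv(out / "sex_dependent.tsv", sep="\t", index=False)

    logger.info("variance structure")
    pv = pvca(ds.subfamily_matrix, variance_threshold=config.pvca_threshold)
    pv.frame().to_csv(out / "pvca.tsv", sep="\t", index=False)
    cl = cluster_samples(ds.subfamily_matrix)
    (out / "dendrogram.nwk").write_text(
        dendrogram_newick(cl.linkage, list(ds.subfamily_matrix.rpkm.columns)))
    cl.labels.rename("cluster").to_csv(out / "cluster_labels.tsv", sep="\t")

    logger.info("gene-TE links")
    nearest = link_tes_to_genes(tes, ds.annotation.genes)
    sets = build_pair_sets(nearest, ds.instance_matrix, ds.gene_matrix,
                           enriched_genes=set(ds.truth.enriched_genes),
                           seed=config.seed)
    pd.concat(sets.values(), ignore_index=True).to_csv(
        out / "gene_te_pairs.tsv", sep="\t", index=False)
    dist_stats = pcc_distribution_analysis(sets, config.cutoff_percentile,
                                           n_boot=config.dip_boot, seed=config.seed)
    dist_stats.to_csv(out / "pair_set_stats.tsv", sep="\t", index=False)
    cutoff = significance_cutoff(sets["background"], config.cutoff_percentile)
    trend = distance_independence(sets["all"], cutoff)

    summary = {
        "seed": config.seed,
        "n_samples": len(enumerate_samples(design)),
        "n_groups": len(enumerate_groups(design, "organ_stage_sex")),
        "expression_classes": {k: int(v) for k, v in classes.counts().items()},
        "n_possible_patterns": len(pattern_alphabet()),
        "pattern_frequencies": {k: int(v) for k, v in
                                pattern_counts(patterns).head(10).items()},
        "n_organ_enriched": len(enr_rows),
        "n_sex_dependent_calls": int((sexdiff["call"] != "none").sum()),
        "pvca_proportions": {k: float(v) for k, v in pv.proportions.items()},
        "cluster_ari_vs_organ": cl.ari,
        "pair_pcc_cutoff": cutoff,
        "distance_trend_pearson_r": trend.pearson_r,
        "compartment_intergenic_fraction": float(comp.loc["all", "Intergenic"]),
    }
    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    return summary
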