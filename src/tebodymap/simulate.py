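"""Seeded synthetic annotation + expression fixtures with planted structure.

The generator emulates a rat body-map style survey at desk scale: a 320
sample factorial design (11 organs x 4 stages x sexes x 4 replicates), a
two-chromosome toy genome with gene models and TE instances placed to
realize configured compartment proportions, and RPKM matrices with
log-normal replicate noise. Known structure is planted so that every
downstream stage can be tested as a recovery problem:

* organ-dominant variance: every subfamily gets a per-organ shift drawn
  from a clipped normal (clipping bounds the shift so that random organ
  structure alone can never reach the 2-fold differential threshold,
  keeping planted effects the only true positives);
* commonly expressed, zero expressed, organ-specific and group-specific
  subfamilies for the expression-class taxonomy;
* organ-enriched (default 8-fold), sex-dependent (male-biased, LTR/DNA)
  and temporally patterned subfamilies for the differential callers;
* gene-TE pairs with target expression correlation, placed in chosen
  compartments and log-spaced TSS-distance strata, with correlation
  independent of distance by construction.

Everything is deterministic given (config, seed): identical configs produce
byte-identical serialized outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, TEInstance
from .design import Group, SampleDesign, enumerate_groups, enumerate_samples
from .expression import ExpressionMatrix

LOG2 = np.log(2.0)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEnriched:
    subfamily: str
    organ: str
    log2_fold: float = 3.0  # 8-fold


@dataclass(frozen=True)
class PlantedSexEffect:
    """Male-biased shift in a single (organ, stage) cell."""

    subfamily: str
    organ: str
    stage: int
    log2_fold: float = 2.0  # 4-fold


@dataclass(frozen=True)
class PlantedPattern:
    """A temporal trajectory (e.g. 'UUU') planted in one organ.

    Stage multipliers are the cumulative step folds, centred on the planted
    baseline; U steps multiply by ``2**step_log2_fold``, D steps divide.
    """

    subfamily: str
    organ: str
    pattern: str
    step_log2_fold: float = 2.0
    baseline_log2: float = 6.0


@dataclass(frozen=True)
class PlantedSpecific:
    """Expressed (~RPKM 8) only in one organ, or one (organ, stage, sex) group."""

    subfamily: str
    organ: str
    stage: int | None = None
    sex: str | None = None


@dataclass(frozen=True)
class PairPlanEntry:
    """A batch of gene-TE pairs sharing compartment, correlation and distance stratum."""

    n_pairs: int
    target_pcc: float
    compartment: str
    min_distance: int = 0  # midpoint-to-TSS, used for intergenic placements
    max_distance: int = 0


def _default_pair_plan() -> tuple[PairPlanEntry, ...]:
    # compartment-graded correlations (UTR > CDS > intron > intergenic) plus
    # distance-independent intergenic strata spanning 1 kb - 1 Mb; the
    # intergenic strata carry 100 pairs each so the distance-trend estimate
    # has standard error ~1/sqrt(400) ~ 0.05
    return (
        PairPlanEntry(30, 0.90, "UTR"),
        PairPlanEntry(30, 0.75, "CDS"),
        PairPlanEntry(30, 0.60, "Intron"),
        PairPlanEntry(100, 0.45, "Intergenic", 1_000, 10_000),
        PairPlanEntry(100, 0.45, "Intergenic", 10_000, 100_000),
        PairPlanEntry(100, 0.45, "Intergenic", 100_000, 500_000),
        PairPlanEntry(100, 0.45, "Intergenic", 500_000, 1_000_000),
    )


#: class composition close to the rat repeat catalogue (LTR-heavy)
DEFAULT_CLASS_PROPORTIONS = {"LTR": 0.70, "DNA": 0.13, "LINE": 0.12, "SINE": 0.05}
FAMILIES = {
    "SINE": ("B1", "B2", "ID"),
    "LINE": ("L1", "L2"),
    "LTR": ("ERV1", "ERVK", "ERVL"),
    "DNA": ("hAT", "TcMar"),
}


def make_catalog(
    n_subfamilies: int = 200,
    class_proportions: dict[str, float] = None,
) -> tuple[tuple[str, str, str], ...]:
    """Deterministic (class, family, subfamily) catalogue."""
    props = class_proportions or DEFAULT_CLASS_PROPORTIONS
    counts = {c: int(round(p * n_subfamilies)) for c, p in props.items()}
    drift = n_subfamilies - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    catalog = []
    for cls_, n in counts.items():
        fams = FAMILIES[cls_]
        for i in range(n):
            fam = fams[i % len(fams)]
            catalog.append((cls_, fam, f"{fam}_{i // len(fams) + 1}"))
    return tuple(catalog)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 800
    n_te_instances: int = 5000
    n_subfamilies: int = 200
    catalog: tuple[tuple[str, str, str], ...] = field(default_factory=make_catalog)
    # expression model (log2 RPKM scale)
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.0
    replicate_cv: float = 0.2
    organ_effect_sd: float = 0.65
    organ_effect_max: float = 0.75  # clip: bounds incidental organ fold changes
    age_effect_sd: float = 0.05
    sex_effect_sd: float = 0.05
    # instance/gene group-profile model
    instance_baseline_log2_mean: float = 4.0
    instance_baseline_log2_sd: float = 0.5
    group_effect_log2_sd: float = 1.5
    # planted effects
    commonly_expressed: tuple[str, ...] = ()
    zero_expressed: tuple[str, ...] = ()
    organ_enriched: tuple[PlantedEnriched, ...] = ()
    sex_dependent: tuple[PlantedSexEffect, ...] = ()
    temporal: tuple[PlantedPattern, ...] = ()
    organ_specific: tuple[PlantedSpecific, ...] = ()
    group_specific: tuple[PlantedSpecific, ...] = ()
    # genome layout
    compartment_proportions: dict[str, float] = field(
        default_factory=lambda: {"CDS": 0.02, "UTR": 0.03, "Intron": 0.30, "Intergenic": 0.65}
    )
    gene_te_correlation_plan: tuple[PairPlanEntry, ...] = field(
        default_factory=_default_pair_plan
    )
    gene_slot_bp: int = 30_000

    def __post_init__(self) -> None:
        if len(self.catalog) != self.n_subfamilies:
            object.__setattr__(self, "catalog", make_catalog(self.n_subfamilies))
        zero = set(self.zero_expressed)
        for name, group in (
            ("commonly_expressed", self.commonly_expressed),
            ("organ_enriched", [e.subfamily for e in self.organ_enriched]),
            ("sex_dependent", [e.subfamily for e in self.sex_dependent]),
            ("temporal", [e.subfamily for e in self.temporal]),
        ):
            clash = zero & set(group)
            if clash:
                raise ValueError(f"zero_expressed overlaps {name}: {sorted(clash)}")
        for e in self.organ_enriched:
            if e.log2_fold <= 0:
                raise ValueError("planted folds must be > 0")
        for e in self.gene_te_correlation_plan:
            if not (0 <= e.target_pcc <= 1):
                raise ValueError("target PCC must be in [0, 1]")

    @property
    def subfamilies(self) -> list[str]:
        return [sf for _, _, sf in self.catalog]

    @property
    def replicate_log2_sd(self) -> float:
        """log2-scale noise sd matching the configured RPKM coefficient of variation."""
        return float(np.sqrt(np.log(1 + self.replicate_cv**2)) / LOG2)


def default_config(seed: int = 0) -> SimulationConfig:
    """The full study-emulation configuration with every planted effect."""
    cat = make_catalog()
    by_class: dict[str, list[str]] = {}
    for cls_, _, sf in cat:
        by_class.setdefault(cls_, []).append(sf)
    take = {c: iter(subs) for c, subs in by_class.items()}

    def pick(cls_: str, n: int) -> list[str]:
        return [next(take[cls_]) for _ in range(n)]

    common = pick("SINE", 8) + pick("DNA", 2) + pick("LTR", 1) + pick("LINE", 1)
    zero = pick("LTR", 33) + pick("LINE", 7)
    enr_subs = pick("LTR", 4) + pick("DNA", 3) + pick("LINE", 3)
    organs = ("Ad", "Br", "He", "Ki", "Li", "Lu", "Mu", "Sp", "Th", "Te")
    enriched = tuple(PlantedEnriched(sf, org) for sf, org in zip(enr_subs, organs))
    sex_cells = [("Ki", 6), ("Li", 6), ("Ki", 21), ("Br", 21), ("Lu", 2), ("He", 104)]
    sex_subs = pick("LTR", 5) + pick("DNA", 1)
    sexdep = tuple(
        PlantedSexEffect(sf, org, st) for sf, (org, st) in zip(sex_subs, sex_cells)
    )
    patterns = ("UUU", "DDD", "UMM", "MMD", "DMM", "MMU")
    temporal = tuple(PlantedPattern(sf, "Br", p) for sf, p in zip(pick("LTR", 6), patterns))
    organ_spec = tuple(PlantedSpecific(sf, "Te") for sf in pick("LTR", 5))
    group_spec = tuple(
        PlantedSpecific(sf, "Li", 6, "male") for sf in pick("LTR", 3)
    )
    return SimulationConfig(
        seed=seed,
        catalog=cat,
        commonly_expressed=tuple(common),
        zero_expressed=tuple(zero),
        organ_enriched=enriched,
        sex_dependent=sexdep,
        temporal=temporal,
        organ_specific=organ_spec,
        group_specific=group_spec,
    )


def null_config(seed: int = 0) -> SimulationConfig:
    """No planted effects and no organ structure: pure replicate noise."""
    return SimulationConfig(seed=seed, organ_effect_sd=0.0, age_effect_sd=0.0,
                            sex_effect_sd=0.0, group_effect_log2_sd=0.0)


def enrichment_recovery_config(seed: int = 0, n_enriched: int = 10) -> SimulationConfig:
    """Only organ-enriched subfamilies planted (the recovery benchmark)."""
    cat = make_catalog()
    subs = [sf for _, _, sf in cat]
    organs = ("Ad", "Br", "He", "Ki", "Li", "Lu", "Mu", "Sp", "Th", "Te", "Ut")
    enriched = tuple(
        PlantedEnriched(subs[i], organs[i % len(organs)]) for i in range(n_enriched)
    )
    return SimulationConfig(seed=seed, catalog=cat, organ_enriched=enriched)


# --------------------------------------------------------------------------
# annotation simulation
# --------------------------------------------------------------------------

@dataclass
class Annotation:
    genes: list[GeneModel]
    tes: list[TEInstance]
    chromosomes: dict[str, int]
    pair_table: pd.DataFrame  # te_id, gene_id, compartment, target_pcc, distance, stratum


def _build_gene(gene_id: str, chrom: str, lo: int, hi: int, strand: str,
                rng: np.random.Generator) -> GeneModel:
    """A 5-exon gene model (UTR, CDS x3, UTR) centred in [lo, hi)."""
    exon_lens = [300, 500, 500, 500, 300]
    intron_lens = rng.integers(800, 2000, size=4)
    span = sum(exon_lens) + int(intron_lens.sum())
    start = (lo + hi - span) // 2
    pos = start
    cds, utr = [], []
    for i, el in enumerate(exon_lens):
        exon = (pos, pos + el)
        (utr if i in (0, 4) else cds).append(exon)
        pos += el
        if i < 4:
            pos += int(intron_lens[i])
    return GeneModel(gene_id, chrom, start, start + span, strand,
                     tuple(cds), tuple(utr))


def _place_in_feature(te_len: int, feature: tuple[int, int], rng: np.random.Generator) -> tuple[int, int]:
    s, e = feature
    te_len = min(te_len, e - s - 2)
    start = int(rng.integers(s, e - te_len))
    return start, start + te_len


def simulate_annotation(config: SimulationConfig) -> Annotation:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    plan = config.gene_te_correlation_plan
    n_pairs = sum(e.n_pairs for e in plan)
    if n_pairs >= config.n_genes:
        raise ValueError("n_genes must exceed the number of planned gene-TE pairs")
    n_regular = config.n_genes - n_pairs

    # chr1: regular genes in fixed slots; chr2: isolated pair-gene slots wide
    # enough that the planted TE's nearest gene is always its own pair gene
    slot1 = config.gene_slot_bp
    chr1_len = n_regular * slot1 + slot1
    max_d = max((e.max_distance for e in plan), default=0)
    slot2 = 2 * max_d + 60_000
    chr2_len = n_pairs * slot2 + slot2 if n_pairs else 0

    genes: list[GeneModel] = []
    for i in range(n_regular):
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(_build_gene(f"gene_{i + 1:04d}", "chr1",
                                 i * slot1, (i + 1) * slot1, strand, rng))
    pair_genes: list[GeneModel] = []
    for j in range(n_pairs):
        strand = "+" if rng.random() < 0.5 else "-"
        pair_genes.append(_build_gene(f"gene_{n_regular + j + 1:04d}", "chr2",
                                      j * slot2, (j + 1) * slot2, strand, rng))
    genes += pair_genes

    tes: list[TEInstance] = []
    catalog = list(config.catalog)
    te_counter = 0

    def new_te(chrom: str, start: int, end: int, strand: str) -> TEInstance:
        nonlocal te_counter
        te_counter += 1
        cls_, fam, sf = catalog[int(rng.integers(len(catalog)))]
        return TEInstance(f"te_{te_counter:05d}", GenomicInterval(chrom, start, end, strand),
                          cls_, fam, sf)

    # planted pair TEs
    pair_rows = []
    j = 0
    for entry in plan:
        for _ in range(entry.n_pairs):
            gene = pair_genes[j]
            j += 1
            te_len = int(rng.integers(150, 400))
            if entry.compartment == "CDS":
                feat = gene.cds_exons[int(rng.integers(len(gene.cds_exons)))]
                start, end = _place_in_feature(te_len, feat, rng)
            elif entry.compartment == "UTR":
                feat = gene.utr_exons[int(rng.integers(len(gene.utr_exons)))]
                start, end = _place_in_feature(te_len, feat, rng)
            elif entry.compartment == "Intron":
                introns = gene.introns
                feat = introns[int(rng.integers(len(introns)))]
                start, end = _place_in_feature(te_len, feat, rng)
            else:  # intergenic, upstream of the TSS at a log-uniform distance
                lo = max(entry.min_distance, te_len // 2 + 10)
                d = int(np.exp(rng.uniform(np.log(lo), np.log(max(entry.max_distance, lo + 1)))))
                mid = gene.start - d if gene.strand == "+" else gene.end - 1 + d
                start, end = mid - te_len // 2, mid - te_len // 2 + te_len
            te = new_te(gene.chrom, start, end, "+" if rng.random() < 0.5 else "-")
            tes.append(te)
            dist = abs(te.interval.midpoint - gene.tss)
            stratum = (f"{entry.min_distance}-{entry.max_distance}"
                       if entry.compartment == "Intergenic" else entry.compartment)
            pair_rows.append(
                {"te_id": te.te_id, "gene_id": gene.gene_id,
                 "compartment": entry.compartment, "target_pcc": entry.target_pcc,
                 "distance": dist, "stratum": stratum}
            )

    # background TEs at the configured compartment proportions
    n_background = config.n_te_instances - n_pairs
    if n_background < 0:
        raise ValueError("n_te_instances smaller than the pair plan")
    props = config.compartment_proportions
    counts = {c: int(round(p * n_background)) for c, p in props.items()}
    counts["Intergenic"] += n_background - sum(counts.values())
    # intergenic gaps on chr1 (complement of gene spans)
    gaps = []
    prev = 0
    for g in sorted((g for g in genes if g.chrom == "chr1"), key=lambda g: g.start):
        if g.start - prev > 1000:
            gaps.append((prev, g.start))
        prev = g.end
    if chr1_len - prev > 1000:
        gaps.append((prev, chr1_len))
    gap_lens = np.array([e - s for s, e in gaps], dtype=float)
    gap_p = gap_lens / gap_lens.sum()
    regular = genes[:n_regular]
    for comp, n in counts.items():
        for _ in range(n):
            te_len = int(rng.integers(150, 400))
            if comp == "Intergenic":
                gi = int(rng.choice(len(gaps), p=gap_p))
                s, e = gaps[gi]
                start, end = _place_in_feature(te_len, (s + 5, e - 5), rng)
                chrom = "chr1"
            else:
                gene = regular[int(rng.integers(n_regular))]
                feats = {"CDS": gene.cds_exons, "UTR": gene.utr_exons,
                         "Intron": gene.introns}[comp]
                feat = feats[int(rng.integers(len(feats)))]
                start, end = _place_in_feature(te_len, feat, rng)
                chrom = gene.chrom
            tes.append(new_te(chrom, start, end, "+" if rng.random() < 0.5 else "-"))

    chroms = {"chr1": chr1_len}
    if n_pairs:
        chroms["chr2"] = chr2_len
    pair_table = pd.DataFrame(
        pair_rows, columns=["te_id", "gene_id", "compartment", "target_pcc",
                            "distance", "stratum"]
    )
    return Annotation(genes, tes, chroms, pair_table)


# --------------------------------------------------------------------------
# expression simulation
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    subfamily_roles: pd.DataFrame  # subfamily, role, organ, stage, sex, pattern, log2_fold
    pair_table: pd.DataFrame  # te_id, gene_id, compartment, target_pcc, distance, stratum
    enriched_genes: tuple[str, ...]  # genes flagged organ-enriched for pair-set building

    def planted(self, role: str) -> pd.DataFrame:
        return self.subfamily_roles[self.subfamily_roles["role"] == role]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    design: SampleDesign
    annotation: Annotation
    subfamily_matrix: ExpressionMatrix
    instance_matrix: ExpressionMatrix
    gene_matrix: ExpressionMatrix
    truth: GroundTruth


def _pattern_stage_offsets(pattern: str, step: float, n_stages: int) -> np.ndarray:
    """Cumulative log2 offsets per stage, centred to mean zero."""
    if len(pattern) != n_stages - 1 or set(pattern) - set("UMD"):
        raise ValueError(f"invalid pattern {pattern!r}")
    offs = [0.0]
    for ch in pattern:
        offs.append(offs[-1] + {"U": step, "M": 0.0, "D": -step}[ch])
    offs = np.array(offs)
    return offs - offs.mean()


def simulate_expression(
    config: SimulationConfig,
    design: SampleDesign,
    annotation: Annotation,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Subfamily, TE-instance and gene RPKM matrices plus the planted truth."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    samples = enumerate_samples(design)
    groups = enumerate_groups(design, "organ_stage_sex")
    g_index = {g.label: i for i, g in enumerate(groups)}
    sample_group = np.array(
        [g_index[Group(s.organ, s.stage, s.sex).label] for s in samples]
    )
    organ_idx = {o: i for i, o in enumerate(design.organs)}
    stage_idx = {st: i for i, st in enumerate(design.stages)}
    g_organ = np.array([organ_idx[g.organ] for g in groups])
    g_stage = np.array([stage_idx[g.stage] for g in groups])
    g_male = np.array([1.0 if g.sex == "male" else -1.0 for g in groups])

    subs = config.subfamilies
    n_sub, n_grp, n_smp = len(subs), len(groups), len(samples)
    sub_idx = {sf: i for i, sf in enumerate(subs)}
    sigma = config.replicate_log2_sd

    roles = pd.DataFrame({"subfamily": subs, "role": "background", "organ": "",
                          "stage": pd.array([pd.NA] * n_sub, dtype="Int64"),
                          "sex": "", "pattern": "", "log2_fold": 0.0}).set_index("subfamily")

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_sub)
    if config.organ_effect_sd > 0:
        organ_eff = np.clip(
            rng.normal(0.0, config.organ_effect_sd, (n_sub, len(design.organs))),
            -config.organ_effect_max, config.organ_effect_max,
        )
    else:
        organ_eff = np.zeros((n_sub, len(design.organs)))
    age_eff = rng.normal(0.0, config.age_effect_sd, (n_sub, len(design.stages))) \
        if config.age_effect_sd > 0 else np.zeros((n_sub, len(design.stages)))
    sex_eff = rng.normal(0.0, config.sex_effect_sd, n_sub) \
        if config.sex_effect_sd > 0 else np.zeros(n_sub)

    silent = np.zeros((n_sub, n_grp), dtype=bool)  # cells drawn below threshold

    for sf in config.commonly_expressed:
        i = sub_idx[sf]
        baseline[i] = 3.5
        roles.loc[sf, "role"] = "common"
    for sf in config.zero_expressed:
        i = sub_idx[sf]
        silent[i, :] = True
        roles.loc[sf, "role"] = "zero"

    # planted effects replace the random organ structure of their subfamily
    mu = baseline[:, None] + organ_eff[:, g_organ] + age_eff[:, g_stage] \
        + sex_eff[:, None] * g_male[None, :] / 2.0

    for e in config.organ_enriched:
        i = sub_idx[e.subfamily]
        mu[i] = baseline[i] + e.log2_fold * (g_organ == organ_idx[e.organ])
        roles.loc[e.subfamily, ["role", "organ", "log2_fold"]] = \
            ["organ_enriched", e.organ, e.log2_fold]
    for e in config.sex_dependent:
        i = sub_idx[e.subfamily]
        boost = e.log2_fold * ((g_organ == organ_idx[e.organ])
                               & (g_stage == stage_idx[e.stage]) & (g_male > 0))
        mu[i] = baseline[i] + boost
        roles.loc[e.subfamily, ["role", "organ", "stage", "sex", "log2_fold"]] = \
            ["sex_dependent", e.organ, e.stage, "male", e.log2_fold]
    for e in config.temporal:
        i = sub_idx[e.subfamily]
        offs = _pattern_stage_offsets(e.pattern, e.step_log2_fold, len(design.stages))
        in_organ = g_organ == organ_idx[e.organ]
        mu[i] = e.baseline_log2 + np.where(in_organ, offs[g_stage], 0.0)
        roles.loc[e.subfamily, ["role", "organ", "pattern", "log2_fold"]] = \
            ["temporal", e.organ, e.pattern, e.step_log2_fold]
    for e in config.organ_specific:
        i = sub_idx[e.subfamily]
        on = g_organ == organ_idx[e.organ]
        mu[i] = 3.0
        silent[i] = ~on
        roles.loc[e.subfamily, ["role", "organ"]] = ["organ_specific", e.organ]
    for e in config.group_specific:
        i = sub_idx[e.subfamily]
        on = ((g_organ == organ_idx[e.organ]) & (g_stage == stage_idx[e.stage])
              & (g_male == (1.0 if e.sex == "male" else -1.0)))
        mu[i] = 3.0
        silent[i] = ~on
        roles.loc[e.subfamily, ["role", "organ", "stage", "sex"]] = \
            ["group_specific", e.organ, e.stage, e.sex]

    noise = rng.normal(0.0, sigma, (n_sub, n_smp))
    rpkm = 2.0 ** (mu[:, sample_group] + noise)
    silent_s = silent[:, sample_group]
    rpkm[silent_s] = rng.uniform(0.0, 0.1, int(silent_s.sum()))
    sample_ids = [s.sample_id for s in samples]
    sub_matrix = ExpressionMatrix(pd.DataFrame(rpkm, index=subs, columns=sample_ids), design)

    # --- instance and gene matrices (group-level latent profiles) ----------
    pair = annotation.pair_table
    te_ids = [t.te_id for t in annotation.tes]
    gene_ids = [g.gene_id for g in annotation.genes]
    s_g = config.group_effect_log2_sd

    te_eta = rng.normal(0.0, 1.0, (len(te_ids), n_grp))
    gene_eta = rng.normal(0.0, 1.0, (len(gene_ids), n_grp))
    te_pos = {t: i for i, t in enumerate(te_ids)}
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for row in pair.itertuples(index=False):
        z = rng.normal(0.0, 1.0, n_grp)
        rho = row.target_pcc
        a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
        te_eta[te_pos[row.te_id]] = a * z + b * rng.normal(0.0, 1.0, n_grp)
        gene_eta[gene_pos[row.gene_id]] = a * z + b * rng.normal(0.0, 1.0, n_grp)

    def expand(eta: np.ndarray, ids: list[str]) -> ExpressionMatrix:
        base = rng.normal(config.instance_baseline_log2_mean,
                          config.instance_baseline_log2_sd, eta.shape[0])
        mu_g = base[:, None] + s_g * eta
        eps = rng.normal(0.0, sigma, (eta.shape[0], n_smp))
        vals = 2.0 ** (mu_g[:, sample_group] + eps)
        return ExpressionMatrix(pd.DataFrame(vals, index=ids, columns=sample_ids), design)

    inst_matrix = expand(te_eta, te_ids)
    gene_matrix = expand(gene_eta, gene_ids)

    truth = GroundTruth(roles.reset_index(), pair.copy(),
                        tuple(pair["gene_id"].tolist()))
    return sub_matrix, inst_matrix, gene_matrix, truth


def simulate_dataset(config: SimulationConfig,
                     design: SampleDesign | None = None) -> SimulatedDataset:
    """Run annotation + expression simulation under one config."""
    design = design or SampleDesign()
    ann = simulate_annotation(config)
    sub, inst, gene, truth = simulate_expression(config, design, ann)
    return SimulatedDataset(config, design, ann, sub, inst, gene, truth)
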