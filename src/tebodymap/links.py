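"""Gene-TE links: nearest gene by TSS distance, expression correlation,
comparison pair sets and distribution analyses.

Each TE instance is linked to the gene whose transcription start site (TSS)
is closest to the TE midpoint. The signed distance follows the gene's
strand: negative means the TE lies 5' (upstream, UTSS) of the TSS, positive
means 3' (downstream, DTSS); a distance of exactly 0 counts as DTSS.
Expression correlation per pair is the Pearson correlation of the
log2(mean RPKM + 1) profiles over the design's (organ, stage, sex) groups
-- group means rather than individual samples, so replicate noise does not
attenuate the correlation.

Four comparison sets mirror the usual empirical-null constructions:
``random`` (a uniform sample of true nearest pairs), ``background``
(random gene x random TE pairings, breaking the nearest relation),
``upstream``/``downstream`` (true nearest pairs of an enriched gene set,
split by side). The background's 95th PCC percentile serves as the
significance cutoff for individual pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, TEInstance
from ._dip import dip_statistic, dip_test
from .expression import ExpressionMatrix, group_mean_rpkm

logger = logging.getLogger(__name__)

PAIR_SET_NAMES = ("all", "random", "background", "upstream", "downstream")


def nearest_gene(te: TEInstance, genes: list[GeneModel]) -> tuple[str, float, str]:
    """Nearest gene of a TE by TSS-to-midpoint distance.

    Returns (gene_id, signed_distance, side). Ties are broken by
    lexicographically smaller gene id. Raises if no gene shares the TE's
    chromosome.
    """
    mid = te.interval.midpoint
    candidates = [g for g in genes if g.chrom == te.interval.chrom]
    if not candidates:
        raise ValueError(f"no gene on chromosome {te.interval.chrom}")
    best = min(candidates, key=lambda g: (abs(mid - g.tss), g.gene_id))
    signed = mid - best.tss if best.strand == "+" else best.tss - mid
    side = "UTSS" if signed < 0 else "DTSS"
    return best.gene_id, signed, side


def link_tes_to_genes(tes: list[TEInstance], genes: list[GeneModel]) -> pd.DataFrame:
    """Nearest-gene table for all TEs (vectorized per chromosome).

    Columns: te_id, gene_id, chrom, signed_distance, side, compartment.
    TEs on chromosomes with no gene are omitted with a logged warning.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index = {}
    for chrom, gs in by_chrom.items():
        gs_sorted = sorted(gs, key=lambda g: (g.tss, g.gene_id))
        index[chrom] = (np.array([g.tss for g in gs_sorted], dtype=float), gs_sorted)
    rows, skipped = [], set()
    for te in tes:
        chrom = te.interval.chrom
        if chrom not in index:
            skipped.add(chrom)
            continue
        tss, gs_sorted = index[chrom]
        mid = te.interval.midpoint
        i = int(np.searchsorted(tss, mid))
        cand = {j for j in (i - 1, i, i + 1) if 0 <= j < len(gs_sorted)}
        best = min((gs_sorted[j] for j in cand),
                   key=lambda g: (abs(mid - g.tss), g.gene_id))
        signed = mid - best.tss if best.strand == "+" else best.tss - mid
        rows.append(
            {"te_id": te.te_id, "gene_id": best.gene_id, "chrom": chrom,
             "signed_distance": signed, "side": "UTSS" if signed < 0 else "DTSS",
             "compartment": te.compartment}
        )
    for chrom in sorted(skipped):
        logger.warning("no gene on chromosome %s; its TEs were skipped", chrom)
    return pd.DataFrame(rows)


def group_profiles(matrix: ExpressionMatrix) -> pd.DataFrame:
    """log2(group-mean RPKM + 1) profiles over the per-sex groups."""
    return np.log2(group_mean_rpkm(matrix) + 1.0)


def pair_pcc(te_profile: np.ndarray, gene_profile: np.ndarray) -> float:
    """Pearson correlation of two aligned group profiles (NaN if degenerate)."""
    te_profile = np.asarray(te_profile, float)
    gene_profile = np.asarray(gene_profile, float)
    if te_profile.shape != gene_profile.shape or te_profile.size < 3:
        raise ValueError("profiles must be aligned with length >= 3")
    if te_profile.std() == 0 or gene_profile.std() == 0:
        return np.nan
    return float(np.corrcoef(te_profile, gene_profile)[0, 1])


def _attach_pcc(pairs: pd.DataFrame, te_prof: pd.DataFrame,
                gene_prof: pd.DataFrame) -> pd.DataFrame:
    t = te_prof.loc[pairs["te_id"]].values
    g = gene_prof.loc[pairs["gene_id"]].values
    tc = t - t.mean(axis=1, keepdims=True)
    gc = g - g.mean(axis=1, keepdims=True)
    denom = np.sqrt((tc**2).sum(axis=1) * (gc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = (tc * gc).sum(axis=1) / denom
    out = pairs.copy()
    out["pcc"] = pcc
    bad = out["pcc"].isna()
    if bad.any():
        logger.info("%d pairs with zero-variance profiles excluded", int(bad.sum()))
    return out[~bad].reset_index(drop=True)


def build_pair_sets(
    nearest: pd.DataFrame,
    te_matrix: ExpressionMatrix,
    gene_matrix: ExpressionMatrix,
    enriched_genes: set[str] | None = None,
    n_random: int = 200,
    n_background: int = 200,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Build the comparison pair sets with PCC attached.

    ``nearest`` is the output of :func:`link_tes_to_genes`. Requested sizes
    are clamped (with a warning) when they exceed the available pairs.
    """
    rng = np.random.default_rng(seed)
    te_prof = group_profiles(te_matrix)
    gene_prof = group_profiles(gene_matrix)
    nearest = nearest[nearest["te_id"].isin(te_prof.index)
                      & nearest["gene_id"].isin(gene_prof.index)].reset_index(drop=True)

    sets: dict[str, pd.DataFrame] = {}
    all_pairs = _attach_pcc(nearest.assign(pair_set="all"), te_prof, gene_prof)
    sets["all"] = all_pairs

    n_rand = min(n_random, len(all_pairs))
    if n_rand < n_random:
        logger.warning("random set clamped to %d pairs", n_rand)
    take = rng.choice(len(all_pairs), size=n_rand, replace=False)
    sets["random"] = all_pairs.iloc[np.sort(take)].assign(pair_set="random").reset_index(drop=True)

    # background: random gene x random TE, the nearest relation broken
    te_ids = all_pairs["te_id"].values
    gene_ids = gene_prof.index.values
    bg_te = te_ids[rng.integers(len(te_ids), size=n_background)]
    bg_gene = gene_ids[rng.integers(len(gene_ids), size=n_background)]
    bg = pd.DataFrame({"te_id": bg_te, "gene_id": bg_gene})
    bg = bg.merge(nearest[["te_id", "chrom", "compartment"]], on="te_id", how="left")
    bg["signed_distance"] = np.nan
    bg["side"] = ""
    bg["pair_set"] = "background"
    sets["background"] = _attach_pcc(bg, te_prof, gene_prof)

    if enriched_genes is not None:
        enr = all_pairs[all_pairs["gene_id"].isin(enriched_genes)]
        sets["upstream"] = enr[enr["side"] == "UTSS"].assign(pair_set="upstream").reset_index(drop=True)
        sets["downstream"] = enr[enr["side"] == "DTSS"].assign(pair_set="downstream").reset_index(drop=True)
    return sets


def significance_cutoff(background: pd.DataFrame, percentile: float = 95.0) -> float:
    """Empirical-null PCC cutoff: a percentile of the background set."""
    return float(np.percentile(background["pcc"].values, percentile))


@dataclass
class DistanceTrendReport:
    n_significant: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    mean_abs_distance_utss: float
    mean_abs_distance_dtss: float
    trend_defined: bool


def distance_independence(pairs: pd.DataFrame, cutoff: float) -> DistanceTrendReport:
    """Correlation between |TSS distance| and PCC among significant pairs.

    A trend near 0 supports distance-independence of the gene-TE
    association. The trend is undefined (flagged) when fewer than 3
    significant pairs remain or distances are constant.
    """
    sig = pairs[(pairs["pcc"] >= cutoff) & pairs["signed_distance"].notna()]
    d = np.abs(sig["signed_distance"].values)
    p = sig["pcc"].values
    utss = np.abs(sig.loc[sig["side"] == "UTSS", "signed_distance"]).mean()
    dtss = np.abs(sig.loc[sig["side"] == "DTSS", "signed_distance"]).mean()
    if len(sig) < 3 or np.ptp(d) == 0 or np.ptp(p) == 0:
        return DistanceTrendReport(len(sig), np.nan, np.nan, np.nan, np.nan,
                                   float(utss), float(dtss), False)
    pr, pp = stats.pearsonr(d, p)
    sr, sp = stats.spearmanr(d, p)
    return DistanceTrendReport(len(sig), float(pr), float(pp), float(sr), float(sp),
                               float(utss), float(dtss), True)


def pcc_distribution_analysis(
    pair_sets: dict[str, pd.DataFrame],
    cutoff_percentile: float = 95.0,
    n_boot: int = 2000,
    seed: int = 0,
    n_bins: int = 40,
    dip_max_n: int = 1000,
) -> pd.DataFrame:
    """Per-set PCC distribution summary with a dip test for bimodality.

    Returns one row per pair set: n, median, dip, dip_p (NaN for sets of
    fewer than 5 pairs), the fraction above the background-derived cutoff,
    and compartment-stratified medians. Sets larger than ``dip_max_n`` are
    subsampled for the dip test to bound the bootstrap cost.
    """
    cutoff = (significance_cutoff(pair_sets["background"], cutoff_percentile)
              if "background" in pair_sets and len(pair_sets["background"]) else np.nan)
    rng = np.random.default_rng(seed)
    rows = []
    for name, df in pair_sets.items():
        pcc = df["pcc"].values
        if len(pcc) == 0:
            continue
        hist, edges = np.histogram(pcc, bins=n_bins, range=(-1, 1))
        if len(pcc) >= 5:
            sample = (pcc if len(pcc) <= dip_max_n
                      else rng.choice(pcc, size=dip_max_n, replace=False))
            dip, dip_p = dip_test(sample, n_boot=n_boot, seed=rng)
        else:
            dip, dip_p = dip_statistic(pcc), np.nan
        row = {
            "pair_set": name,
            "n": len(pcc),
            "median_pcc": float(np.median(pcc)),
            "dip": dip,
            "dip_p": dip_p,
            "cutoff": cutoff,
            "frac_above_cutoff": float(np.mean(pcc >= cutoff)) if np.isfinite(cutoff) else np.nan,
        }
        for comp, sub in df.groupby("compartment"):
            if comp:
                row[f"median_pcc_{comp}"] = float(sub["pcc"].median())
        rows.append(row)
    return pd.DataFrame(rows)
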