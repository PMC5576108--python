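"""Nearest-gene linking, pair correlation, pair sets and distance analyses."""

import numpy as np
import pandas as pd
import pytest

from tebodymap.annotation import GeneModel, GenomicInterval, TEInstance
from tebodymap.links import (build_pair_sets, distance_independence,
                             link_tes_to_genes, nearest_gene, pair_pcc,
                             significance_cutoff)


def gene(gene_id, tss, strand="+", chrom="chr1", length=400):
    if strand == "+":
        return GeneModel(gene_id, chrom, tss, tss + length, strand)
    return GeneModel(gene_id, chrom, tss - length + 1, tss + 1, strand)


def te(te_id, start, end, chrom="chr1"):
    return TEInstance(te_id, GenomicInterval(chrom, start, end), "SINE", "B1", "B1_1")


class TestNearestGene:
    def test_plus_strand_downstream(self):
        genes = [gene("g1", 400, "+"), gene("g2", 1000, "+")]
        gid, signed, side = nearest_gene(te("t", 450, 550), genes)
        assert (gid, signed, side) == ("g1", 100.0, "DTSS")

    def test_minus_strand_sign_flips(self):
        # midpoint 500, TSS 600 on '-' strand: downstream means lower coords
        genes = [gene("g1", 600, "-")]
        gid, signed, side = nearest_gene(te("t", 450, 550), genes)
        assert (gid, signed, side) == ("g1", 100.0, "DTSS")

    def test_plus_strand_upstream(self):
        genes = [gene("g1", 600, "+")]
        gid, signed, side = nearest_gene(te("t", 450, 550), genes)
        assert (gid, signed, side) == ("g1", -100.0, "UTSS")

    def test_equidistant_tie_breaks_lexicographically(self):
        genes = [gene("gB", 400, "+"), gene("gA", 600, "+")]
        gid, signed, side = nearest_gene(te("t", 450, 550), genes)
        assert gid == "gA"

    def test_zero_distance_is_dtss(self):
        genes = [gene("g1", 500, "+")]
        _, signed, side = nearest_gene(te("t", 450, 550), genes)
        assert signed == 0.0 and side == "DTSS"

    def test_no_gene_on_chromosome(self):
        with pytest.raises(ValueError, match="no gene"):
            nearest_gene(te("t", 0, 10, "chrX"), [gene("g1", 100)])


def test_link_table_matches_bruteforce_oracle():
    """Vectorized linking equals per-TE exhaustive search on 1,000 random TEs."""
    rng = np.random.default_rng(0)
    genes = []
    for i in range(60):
        chrom = f"chr{rng.integers(1, 4)}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(gene(f"g{i:03d}", int(rng.integers(1000, 500_000)), strand, chrom))
    tes = [te(f"t{i:04d}", s := int(rng.integers(0, 500_000)),
              s + int(rng.integers(100, 400)), f"chr{rng.integers(1, 4)}")
           for i in range(1000)]
    table = link_tes_to_genes(tes, genes).set_index("te_id")
    for t_ in tes:
        gid, signed, side = nearest_gene(t_, genes)
        row = table.loc[t_.te_id]
        assert row["gene_id"] == gid
        assert row["signed_distance"] == signed
        assert row["side"] == side
    # side/sign consistency
    assert ((table["signed_distance"] < 0) == (table["side"] == "UTSS")).all()


def test_tes_on_geneless_chromosome_skipped(caplog):
    with caplog.at_level("WARNING"):
        table = link_tes_to_genes([te("t", 0, 10, "chrUn")], [gene("g1", 100)])
    assert len(table) == 0


class TestPairPcc:
    def test_identical_profiles(self):
        x = np.arange(10.0)
        assert pair_pcc(x, x) == pytest.approx(1.0)

    def test_negated_profiles(self):
        x = np.arange(10.0)
        assert pair_pcc(x, -x) == pytest.approx(-1.0)

    def test_degenerate_profile_is_nan(self):
        assert np.isnan(pair_pcc(np.ones(10), np.arange(10.0)))

    def test_short_profiles_rejected(self):
        with pytest.raises(ValueError, match="length >= 3"):
            pair_pcc(np.ones(2), np.ones(2))


class TestPairSets:
    def test_same_seed_identical_sets(self, default_ds, nearest_table):
        kw = dict(te_matrix=default_ds.instance_matrix,
                  gene_matrix=default_ds.gene_matrix,
                  enriched_genes=set(default_ds.truth.enriched_genes), seed=7)
        a = build_pair_sets(nearest_table, **kw)
        b = build_pair_sets(nearest_table, **kw)
        for name in a:
            pd.testing.assert_frame_equal(a[name], b[name])

    def test_upstream_downstream_tile_enriched_pairs(self, default_ds, nearest_table):
        sets = build_pair_sets(nearest_table, default_ds.instance_matrix,
                               default_ds.gene_matrix,
                               enriched_genes=set(default_ds.truth.enriched_genes),
                               seed=0)
        enriched_all = sets["all"][
            sets["all"]["gene_id"].isin(default_ds.truth.enriched_genes)]
        assert len(sets["upstream"]) + len(sets["downstream"]) == len(enriched_all)
        assert (sets["upstream"]["side"] == "UTSS").all()
        assert (sets["downstream"]["side"] == "DTSS").all()

    def test_background_centered_at_zero(self, default_ds, nearest_table):
        sets = build_pair_sets(nearest_table, default_ds.instance_matrix,
                               default_ds.gene_matrix, n_background=400, seed=0)
        assert abs(sets["background"]["pcc"].median()) < 0.1

    def test_requested_size_clamped(self, default_ds, nearest_table, caplog):
        with caplog.at_level("WARNING"):
            sets = build_pair_sets(nearest_table.head(50), default_ds.instance_matrix,
                                   default_ds.gene_matrix, n_random=10_000, seed=0)
        assert len(sets["random"]) == len(sets["all"])

    def test_no_duplicate_pairs_within_sets(self, default_ds, nearest_table):
        sets = build_pair_sets(nearest_table, default_ds.instance_matrix,
                               default_ds.gene_matrix, seed=0)
        for name in ("all", "random"):
            assert not sets[name].duplicated(["te_id", "gene_id"]).any()


def test_cutoff_definition_keeps_five_percent_of_background(default_ds, nearest_table):
    sets = build_pair_sets(nearest_table, default_ds.instance_matrix,
                           default_ds.gene_matrix, n_background=400, seed=0)
    cut = significance_cutoff(sets["background"], 95.0)
    frac = (sets["background"]["pcc"] >= cut).mean()
    assert frac == pytest.approx(0.05, abs=0.01)


class TestDistanceIndependence:
    def _pairs(self, d, p, side="UTSS"):
        return pd.DataFrame({"te_id": [f"t{i}" for i in range(len(d))],
                             "gene_id": "g", "signed_distance": -np.asarray(d),
                             "side": side, "pcc": p})

    def test_flat_correlation_gives_null_trend(self):
        rng = np.random.default_rng(1)
        d = 10 ** rng.uniform(2, 6, 300)
        p = 0.6 + rng.normal(0, 0.05, 300)
        rep = distance_independence(self._pairs(d, p), cutoff=0.3)
        assert rep.trend_defined
        assert abs(rep.pearson_r) < 0.1

    def test_decaying_correlation_detected(self):
        rng = np.random.default_rng(2)
        d = 10 ** rng.uniform(2, 6, 300)
        p = 0.9 - 0.1 * np.log10(d) + rng.normal(0, 0.03, 300)
        rep = distance_independence(self._pairs(d, p), cutoff=0.0)
        assert rep.spearman_rho < -0.5 and rep.spearman_p < 1e-6

    def test_single_stratum_flagged_undefined(self):
        rep = distance_independence(self._pairs([1000.0] * 30, [0.5] * 30), cutoff=0.0)
        assert not rep.trend_defined
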