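"""Differential calling: the FC + Bonferroni rule and its derived callers."""

import numpy as np
import pandas as pd
import pytest

from tebodymap.design import Group, enumerate_samples
from tebodymap.differential import (dete_test, development_dependent,
                                    development_dependent_set, organ_enriched,
                                    pattern_counts, sex_dependent,
                                    temporal_pattern)
from tebodymap.design import pattern_alphabet
from tebodymap.expression import ExpressionMatrix
from .conftest import make_design, matrix_from_cells


def _noisy_matrix(design, cells, features, seed=0, cv_sd=0.287):
    return matrix_from_cells(design, cells, features, noise_sd=cv_sd, seed=seed)


class TestDeteTest:
    def test_identical_groups_fc_one_call_none(self, small_design):
        m = matrix_from_cells(small_design, {"f": {"*": 4.0}}, ["f"])
        res = dete_test(m, Group("O0", 2), Group("O1", 2))
        assert res.loc[0, "fold_change"] == pytest.approx(1.0)
        assert res.loc[0, "p_raw"] == 1.0  # degenerate equal means
        assert res.loc[0, "call"] == "none"

    def test_large_fc_without_significance_is_none(self, small_design):
        # high variance within groups: FC >= 2 but p large
        rng = np.random.default_rng(0)
        samples = enumerate_samples(small_design)
        vals = {s.sample_id: [rng.choice([0.1, 60.0])] for s in samples}
        m = ExpressionMatrix(pd.DataFrame(vals, index=["f"]), small_design)
        res = dete_test(m, Group("O0", 2), Group("O1", 2), m_tests=200)
        if res.loc[0, "p_bonferroni"] > 0.05:
            assert res.loc[0, "call"] == "none"

    def test_planted_fourfold_shift_recovered(self):
        """>= 90% of 4-fold planted features called over (cv 0.2, n=4, m=200)."""
        d = make_design(n_organs=2, stages=(2,))
        planted = [f"p{i}" for i in range(100)]
        nulls = [f"n{i}" for i in range(100)]
        cells = {f: {"*": 8.0, ("O0", 2, "male"): 32.0, ("O0", 2, "female"): 32.0}
                 for f in planted}
        cells.update({f: {"*": 8.0} for f in nulls})
        m = _noisy_matrix(d, cells, planted + nulls, seed=1)
        res = dete_test(m, Group("O0", 2), Group("O1", 2), m_tests=200)
        calls = res.set_index("feature")["call"]
        assert (calls.loc[planted] == "over").mean() >= 0.9
        assert (calls.loc[nulls] != "none").mean() <= 0.05

    def test_symmetry_over_under(self, small_design):
        rng = np.random.default_rng(2)
        samples = enumerate_samples(small_design)
        df = pd.DataFrame(rng.random((50, len(samples))) * 20,
                          index=[f"f{i}" for i in range(50)],
                          columns=[s.sample_id for s in samples])
        m = ExpressionMatrix(df, small_design)
        ab = dete_test(m, Group("O0", 6), Group("O1", 6))
        ba = dete_test(m, Group("O1", 6), Group("O0", 6))
        assert np.allclose(ab["fold_change"] * 0 + ab["p_raw"], ba["p_raw"])
        swap = {"over": "under", "under": "over", "none": "none"}
        assert list(ab["call"].map(swap)) == list(ba["call"])

    def test_bonferroni_monotone_in_family_size(self, small_design):
        rng = np.random.default_rng(3)
        samples = enumerate_samples(small_design)
        df = pd.DataFrame(rng.random((80, len(samples))) * 20,
                          index=[f"f{i}" for i in range(80)],
                          columns=[s.sample_id for s in samples])
        m = ExpressionMatrix(df, small_design)
        small = dete_test(m, Group("O0", 6), Group("O1", 6), m_tests=10)
        big = dete_test(m, Group("O0", 6), Group("O1", 6), m_tests=1000)
        became_called = (small["call"] == "none") & (big["call"] != "none")
        assert not became_called.any()
        assert (big["p_bonferroni"] >= small["p_bonferroni"]).all()

    def test_rejects_degenerate_groups(self, small_design):
        m = matrix_from_cells(small_design, {"f": {"*": 1.0}}, ["f"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            dete_test(m, [m.rpkm.columns[0]], Group("O1", 2))
        with pytest.raises(ValueError, match="m_tests"):
            dete_test(m, Group("O0", 2), Group("O1", 2), m_tests=0)


class TestOrganEnriched:
    def test_strict_intersection(self):
        d = make_design(n_organs=3, stages=(2,))
        cells = {
            # over vs both others -> enriched
            "enr": {"*": 4.0, ("O0", 2, "male"): 64.0, ("O0", 2, "female"): 64.0},
            # over vs O1 only, tied with O2 -> not enriched
            "half": {"*": 4.0, ("O0", 2, "male"): 64.0, ("O0", 2, "female"): 64.0,
                     ("O2", 2, "male"): 64.0, ("O2", 2, "female"): 64.0},
            "flat": {"*": 4.0},
        }
        m = _noisy_matrix(d, cells, list(cells), seed=4)
        enr = organ_enriched(m, stage=2, m_tests=3)
        assert enr["O0"] == {"enr"}
        assert "half" not in enr["O0"]

    def test_recovery_with_planted_folds(self, default_ds):
        """Planted fold-8 subfamilies are found in their organ at every stage."""
        truth = default_ds.truth.planted("organ_enriched")
        for stage in default_ds.design.stages:
            enr = organ_enriched(default_ds.subfamily_matrix, stage)
            for row in truth.itertuples():
                assert row.subfamily in enr[row.organ]


class TestDevelopmentDependent:
    def test_all_six_stage_pairs_emitted(self, default_ds):
        res = development_dependent(default_ds.subfamily_matrix, "Ad")
        assert res["comparison"].nunique() == 6

    def test_flat_trajectory_empty_set(self):
        d = make_design(n_organs=1)
        m = _noisy_matrix(d, {"f": {"*": 8.0}}, ["f"], seed=5)
        res = development_dependent(m, "O0", m_tests=200)
        assert development_dependent_set(res) == set()

    def test_single_jump_appears_in_matching_pairs(self):
        d = make_design(n_organs=1)
        cells = {"f": {("O0", st, sx): (4.0 if st == 2 else 32.0)
                       for st in d.stages for sx in ("male", "female")}}
        m = _noisy_matrix(d, cells, ["f"], seed=6)
        res = development_dependent(m, "O0", m_tests=1)
        called = set(res.loc[res["call"] != "none", "comparison"])
        assert called == {"O0_6w_vs_2w", "O0_21w_vs_2w", "O0_104w_vs_2w"}


class TestSexDependent:
    def test_single_sex_organs_skipped(self, design):
        from tebodymap.simulate import default_config, simulate_dataset
        # use a tiny matrix on the full design
        m = matrix_from_cells(design, {"f": {"*": 4.0}}, ["f"])
        res = sex_dependent(m)
        assert set(res["organ"]) == set(design.organs) - {"Te", "Ut"}
        assert len(res) == 36  # 9 organs x 4 stages, one feature each

    def test_identical_sexes_not_called(self, small_design):
        m = matrix_from_cells(small_design, {"f": {"*": 4.0}}, ["f"])
        assert (sex_dependent(m)["call"] == "none").all()

    def test_planted_male_bias_called_in_its_cell(self):
        d = make_design(n_organs=2)
        cells = {"f": {"*": 8.0, ("O0", 6, "male"): 64.0}}
        m = _noisy_matrix(d, cells, ["f"], seed=7)
        res = sex_dependent(m, m_tests=1)
        called = res[res["call"] != "none"]
        assert list(zip(called["organ"], called["stage"])) == [("O0", 6)]
        assert (called["call"] == "over").all()  # male is the numerator


class TestTemporalPattern:
    def test_constant_trajectory_is_mmm(self):
        d = make_design(n_organs=1)
        m = _noisy_matrix(d, {"f": {"*": 8.0}}, ["f"], seed=8)
        pat = temporal_pattern(m, "O0")
        assert pat.loc[0, "pattern"] == "MMM"

    def test_planted_monotone_trajectories(self):
        d = make_design(n_organs=1)
        up = {("O0", st, sx): 2.0 * 8 ** i
              for i, st in enumerate(d.stages) for sx in ("male", "female")}
        down = {("O0", st, sx): 1024.0 / 8 ** i
                for i, st in enumerate(d.stages) for sx in ("male", "female")}
        m = _noisy_matrix(d, {"up": up, "down": down}, ["up", "down"], seed=9)
        pat = temporal_pattern(m, "O0", m_tests=2).set_index("subfamily")
        assert pat.loc["up", "pattern"] == "UUU"
        assert pat.loc["down", "pattern"] == "DDD"

    def test_output_range_within_27_labels(self, default_ds):
        pat = temporal_pattern(default_ds.subfamily_matrix, "Br")
        assert set(pat["pattern"]) <= set(pattern_alphabet())
        assert pattern_counts(pat).idxmax() == "MMM"

    def test_planted_patterns_recovered(self, default_ds):
        truth = default_ds.truth.planted("temporal")
        pat = temporal_pattern(default_ds.subfamily_matrix, "Br").set_index("subfamily")
        for row in truth.itertuples():
            assert pat.loc[row.subfamily, "pattern"] == row.pattern
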