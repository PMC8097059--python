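"""Moderated tests, permutation/BH FDR and the volcano prioritization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from kinsig import (
    FunctionalScoreTable,
    QuantMatrix,
    SampleDesign,
    SamParams,
    anova_oneway,
    bh_adjust,
    moderated_t_two_class,
    one_sample_t,
    permutation_fdr,
    prioritize_functional,
    proteome_correction_flags,
    sam_test,
    volcano_select,
)

from oracles import anova_f, bh_stepup, permutation_q


def make_matrix(values: np.ndarray, design: SampleDesign) -> QuantMatrix:
    return QuantMatrix(pd.DataFrame(
        values, index=[f"f{i:03d}" for i in range(len(values))],
        columns=design.sample_ids))


class TestModeratedT:
    def test_closed_form_example(self, two_group_design):
        m = make_matrix(np.array([[2.0, 3.0, 4.0, 0.0, 1.0, 2.0]]),
                        two_group_design)
        res = moderated_t_two_class(m, two_group_design, "case", "control",
                                    s0=0.1)
        assert res["log2fc"].iloc[0] == pytest.approx(2.0)
        se = np.sqrt(2.0 / 3.0)
        assert res["statistic"].iloc[0] == pytest.approx(2.0 / (se + 0.1))

    def test_identical_means_give_zero(self, two_group_design):
        m = make_matrix(np.array([[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]]),
                        two_group_design)
        res = moderated_t_two_class(m, two_group_design, "case", "control")
        assert res["statistic"].iloc[0] == 0.0

    def test_s0_zero_is_student_t(self, two_group_design):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(15, 6))
        m = make_matrix(vals, two_group_design)
        res = moderated_t_two_class(m, two_group_design, "case", "control",
                                    s0=0.0)
        expected = stats.ttest_ind(vals[:, :3], vals[:, 3:], axis=1).statistic
        np.testing.assert_allclose(res["statistic"], expected, atol=1e-12)

    def test_underobserved_feature_unscored(self, two_group_design):
        vals = np.array([[1.0, np.nan, np.nan, 0.0, 1.0, 2.0]])
        m = make_matrix(vals, two_group_design)
        res = moderated_t_two_class(m, two_group_design, "case", "control")
        assert np.isnan(res["statistic"].iloc[0])

    def test_unknown_group_rejected(self, two_group_design, small_matrix):
        with pytest.raises(KeyError):
            moderated_t_two_class(small_matrix, two_group_design,
                                  "case", "nonexistent")


class TestPermutationFdr:
    def test_matches_exhaustive_oracle(self, two_group_design):
        """20 features, 3 vs 3: all 20 label splits enumerated on both sides."""
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(20, 6))
        vals[:3, :3] += 2.5  # a few real effects
        m = make_matrix(vals, two_group_design)
        params = SamParams(s0=0.1, n_permutations=250, fdr_target=0.05, seed=0)
        res = moderated_t_two_class(m, two_group_design, "case", "control", 0.1)
        q, _ = permutation_fdr(res["statistic"], m, two_group_design,
                               "case", "control", params)
        expected = permutation_q(vals, n_case=3, s0=0.1)
        np.testing.assert_allclose(q.to_numpy(), expected, atol=1e-12)

    def test_exhaustive_is_seed_independent(self, two_group_design):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(size=(10, 6)), two_group_design)
        res = moderated_t_two_class(m, two_group_design, "case", "control", 0.1)
        qs = [permutation_fdr(res["statistic"], m, two_group_design, "case",
                              "control", SamParams(seed=s))[0] for s in (0, 99)]
        pd.testing.assert_series_equal(qs[0], qs[1])

    def test_constant_features_not_significant(self, two_group_design):
        vals = np.full((5, 6), 3.14)
        m = make_matrix(vals, two_group_design)
        res = sam_test(m, two_group_design, "case", "control")
        assert not res["significant"].any()
        assert (res["q"] == 1.0).all()

    def test_extreme_feature_called(self, two_group_design):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.2, size=(400, 6))
        vals[0, :3] += 50.0  # one feature far above every permuted value
        m = make_matrix(vals, two_group_design)
        res = sam_test(m, two_group_design, "case", "control",
                       SamParams(fdr_target=0.05, seed=0))
        assert bool(res["significant"].iloc[0])

    def test_degenerate_design_rejected(self):
        design = SampleDesign(pd.DataFrame(
            [("a", "case", 1, "case"), ("b", "control", 1, "control"),
             ("c", "control", 2, "control")],
            columns=["sample_id", "condition", "replicate", "group_role"]))
        m = QuantMatrix(pd.DataFrame(np.ones((3, 3)), index=list("xyz"),
                                     columns=["a", "b", "c"]))
        res = moderated_t_two_class(m, design, "case", "control")
        with pytest.raises(ValueError, match="at least 2"):
            permutation_fdr(res["statistic"], m, design, "case", "control",
                            SamParams())

    def test_row_order_invariance(self, two_group_design):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(30, 6))
        vals[:5, :3] += 3.0
        m = make_matrix(vals, two_group_design)
        res = sam_test(m, two_group_design, "case", "control")
        perm = rng.permutation(30)
        m2 = QuantMatrix(m.data.iloc[perm])
        res2 = sam_test(m2, two_group_design, "case", "control")
        sig1 = set(res.index[res["significant"]])
        sig2 = set(res2.index[res2["significant"]])
        assert sig1 == sig2


class TestAnova:
    def test_two_groups_equal_pooled_t_squared(self, two_group_design):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(12, 6))
        m = make_matrix(vals, two_group_design)
        res = anova_oneway(m, two_group_design)
        t = stats.ttest_ind(vals[:, :3], vals[:, 3:], axis=1)
        np.testing.assert_allclose(res["statistic"], t.statistic**2, atol=1e-10)
        np.testing.assert_allclose(res["p"], t.pvalue, atol=1e-12)

    def test_three_group_closed_form(self):
        design = SampleDesign(pd.DataFrame(
            [(f"{c}_{r}", c, r, "other") for c in ("g1", "g2", "g3")
             for r in (1, 2, 3)],
            columns=["sample_id", "condition", "replicate", "group_role"]))
        groups = [[-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0], [2.0, 3.0, 4.0]]
        vals = np.array([sum(groups, [])])
        m = QuantMatrix(pd.DataFrame(vals, index=["f"],
                                     columns=design.sample_ids))
        res = anova_oneway(m, design)
        assert res["statistic"].iloc[0] == pytest.approx(anova_f(groups))

    def test_constant_feature_excluded_from_bh(self, two_group_design):
        vals = np.vstack([np.ones(6), np.random.default_rng(0).normal(size=6)])
        m = make_matrix(vals, two_group_design)
        res = anova_oneway(m, two_group_design)
        assert np.isnan(res["p"].iloc[0])
        # BH family of size 1: q equals p for the remaining feature
        assert res["q"].iloc[1] == pytest.approx(res["p"].iloc[1])

    def test_null_p_uniform(self, two_group_design):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.normal(size=(600, 6)), two_group_design)
        res = anova_oneway(m, two_group_design)
        ks = stats.kstest(res["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01


class TestOneSampleT:
    def test_zero_ratios_give_zero(self):
        m = QuantMatrix(pd.DataFrame([[0.0] * 4], index=["f"],
                                     columns=list("abcd")))
        res = one_sample_t(m, s0=0.1)
        assert res["statistic"].iloc[0] == 0.0

    def test_zero_variance_regularized_by_s0(self):
        m = QuantMatrix(pd.DataFrame([[1.0] * 4], index=["f"],
                                     columns=list("abcd")))
        res = one_sample_t(m, s0=0.1)
        assert res["statistic"].iloc[0] == pytest.approx(10.0)

    def test_s0_zero_is_classical_t(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0.3, 1.0, size=(25, 5))
        m = QuantMatrix(pd.DataFrame(vals, index=[f"f{i}" for i in range(25)],
                                     columns=list("abcde")))
        res = one_sample_t(m, s0=0.0)
        t = stats.ttest_1samp(vals, 0.0, axis=1)
        np.testing.assert_allclose(res["statistic"], t.statistic, atol=1e-12)
        np.testing.assert_allclose(res["p"], t.pvalue, atol=1e-12)

    def test_single_observation_unscored(self):
        m = QuantMatrix(pd.DataFrame([[1.0, np.nan, np.nan]], index=["f"],
                                     columns=list("abc")))
        res = one_sample_t(m)
        assert np.isnan(res["statistic"].iloc[0])


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.05])), [0.05])

    def test_stepup_hand_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    def test_missing_excluded_from_family(self):
        q = bh_adjust(pd.Series([0.02, np.nan, 0.04]))
        np.testing.assert_allclose(q.dropna(), bh_stepup([0.02, 0.04]))
        assert np.isnan(q.iloc[1])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_stepup_oracle(self, pvals):
        got = bh_adjust(np.array(pvals))
        expected = bh_stepup(pvals)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert (got >= np.array(pvals) - 1e-15).all()


class TestVolcano:
    def _result(self, fcs, qs):
        ids = [f"s{i:02d}" for i in range(len(fcs))]
        return pd.DataFrame({"log2fc": fcs, "q": qs}, index=ids)

    def test_hand_computed_up_threshold_excludes_all(self):
        res = self._result([0.1, 0.2, 0.3, 3.0], [0.001] * 4)
        with pytest.warns(UserWarning):  # no negative side
            sel = volcano_select(res, fdr=0.01)
        assert sel.up_threshold == pytest.approx(3 * np.std(
            [0.1, 0.2, 0.3, 3.0], ddof=1))
        assert sel.up_threshold == pytest.approx(4.2073, abs=2e-4)
        assert sel.selected == []

    def test_degenerate_zero_sd_selects_all_passing_q(self):
        res = self._result([0.5, 0.5, 0.5, -1.0, -2.0], [0.001, 0.5, 0.001,
                                                         0.9, 0.9])
        sel = volcano_select(res, fdr=0.01)
        assert sel.up_threshold == 0.0
        assert set(sel.selected) == {"s00", "s02"}

    def test_symmetric_distribution_gives_equal_thresholds(self):
        rng = np.random.default_rng(0)
        fc = rng.normal(size=2000)
        fc = np.concatenate([fc, -fc])  # exactly symmetric
        res = self._result(fc, np.full(len(fc), 0.5))
        sel = volcano_select(res, fdr=0.01)
        assert sel.up_threshold == pytest.approx(sel.down_threshold, rel=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        fc = rng.normal(size=50)
        qs = rng.uniform(size=50)
        a = volcano_select(self._result(fc, qs), fdr=0.2)
        b_tab = self._result(fc, qs)
        b_tab.index = [f"renamed_{i}" for i in range(50)]
        b = volcano_select(b_tab, fdr=0.2)
        assert (a.table["selected"].to_numpy()
                == b.table["selected"].to_numpy()).all()


class TestProteomeCorrectionAndFunctional:
    def _selection(self, fcs, qs, ids):
        return volcano_select(pd.DataFrame({"log2fc": fcs, "q": qs}, index=ids),
                              fdr=0.05)

    def test_flag_requires_same_direction_selection(self):
        rng = np.random.default_rng(7)
        site_fc = np.concatenate([[8.0, 8.0, -8.0], rng.normal(0, 0.1, 200)])
        site_q = np.concatenate([[0.001] * 3, np.full(200, 0.9)])
        sites = ["PA_S1", "PB_S2", "PC_S3"] + [f"PX{i}_S9" for i in range(200)]
        sel = self._selection(site_fc, site_q, sites)
        prot_fc = np.concatenate([[8.0, 0.0, -8.0], rng.normal(0, 0.1, 200)])
        prot_q = np.concatenate([[0.001, 0.9, 0.001], np.full(200, 0.9)])
        prots = ["PA", "PB", "PC"] + [f"PX{i}" for i in range(200)]
        prot_sel = self._selection(prot_fc, prot_q, prots)
        mapping = {s: s.rsplit("_", 1)[0] for s in sites}
        out = proteome_correction_flags(sel, mapping, prot_sel)
        tab = out.table
        assert bool(tab.loc["PA_S1", "proteome_regulated"])   # both up
        assert not bool(tab.loc["PB_S2", "proteome_regulated"])  # protein flat
        assert bool(tab.loc["PC_S3", "proteome_regulated"])   # both down

    def test_brute_force_oracle_on_toy_table(self):
        """10 sites on 4 proteins against an oracle applying both rules."""
        rng = np.random.default_rng(21)
        prots = ["A", "B", "C", "D"]
        sites = [f"{p}_S{i}" for i, p in enumerate(
            ["A", "A", "B", "B", "B", "C", "C", "D", "D", "D"], start=1)]
        site_fc = rng.normal(0, 2.0, 10)
        site_q = rng.uniform(0, 0.1, 10)
        prot_fc = rng.normal(0, 2.0, 4)
        prot_q = rng.uniform(0, 0.1, 4)
        sel = self._selection(site_fc, site_q, sites)
        prot_sel = self._selection(prot_fc, prot_q, prots)
        mapping = {s: s.split("_")[0] for s in sites}
        out = proteome_correction_flags(sel, mapping, prot_sel).table

        def rule(fc, q, pos, neg):
            if q >= 0.05 or fc == 0:
                return None
            if fc > 0:
                return "up" if pos is not None and fc > pos else None
            return "down" if neg is not None and -fc > neg else None

        def side_sd(arr, positive):
            side = arr[arr > 0] if positive else -arr[arr < 0]
            return 3 * side.std(ddof=1) if len(side) >= 2 else None

        sp, sn = side_sd(site_fc, True), side_sd(site_fc, False)
        pp, pn = side_sd(prot_fc, True), side_sd(prot_fc, False)
        for site, fc, q in zip(sites, site_fc, site_q):
            s_dir = rule(fc, q, sp, sn)
            prot = mapping[site]
            p_dir = rule(prot_fc[prots.index(prot)], prot_q[prots.index(prot)],
                         pp, pn)
            expected = s_dir is not None and s_dir == p_dir
            assert bool(out.loc[site, "proteome_regulated"]) == expected, site

    def test_functional_filter_strict_threshold(self):
        sel = self._selection([5.0, 5.0, 5.0, -0.1, -0.2, -0.3, -0.25],
                              [0.001] * 7,
                              [f"P{i}_S1" for i in range(7)])
        scores = FunctionalScoreTable({"P0_S1": 0.51, "P1_S1": 0.50})
        out = prioritize_functional(sel, scores, min_score=0.5)
        assert out.prioritized == ["P0_S1"]
        assert out.table.loc["P2_S1", "provenance"] == "unscored"

    def test_all_scores_one_keeps_selected_set(self):
        ids = [f"P{i}_S1" for i in range(6)]
        sel = self._selection([1.0, 1.0, 1.0, -1.0, -1.0, -1.0],
                              [0.001] * 6, ids)
        assert len(sel.selected) == 6  # both side SDs are 0
        scores = FunctionalScoreTable({s: 1.0 for s in ids})
        out = prioritize_functional(sel, scores)
        assert set(out.prioritized) == set(sel.selected)
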