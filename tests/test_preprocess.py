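"""Normalization, filtering, ratios, PCA and hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform

from kinsig import (
    QuantMatrix,
    filter_by_completeness,
    hierarchical_cluster,
    make_log2_ratios_vs_reference,
    normalize_median_center,
    run_pca,
    scale_rows_z,
)

from oracles import average_linkage_merges


def qm(rows: dict, columns: list[str]) -> QuantMatrix:
    return QuantMatrix(pd.DataFrame.from_dict(rows, orient="index",
                                              columns=columns))


class TestMedianCenter:
    def test_median_shift(self):
        m = qm({"a": [1.0], "b": [2.0], "c": [3.0]}, ["s1"])
        out, report = normalize_median_center(m)
        assert out.data["s1"].tolist() == [-1.0, 0.0, 1.0]
        assert report.median_before["s1"] == 2.0
        assert abs(report.median_after["s1"]) < 1e-9

    def test_idempotent_on_centered_data(self):
        m = qm({"a": [-1.0, 2.0], "b": [0.0, 0.0], "c": [1.0, -2.0]},
               ["s1", "s2"])
        out, _ = normalize_median_center(m)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_median_over_observed_values_only(self):
        m = qm({"a": [5.0], "b": [np.nan], "c": [7.0]}, ["s1"])
        out, _ = normalize_median_center(m)
        assert out.data["s1"].tolist()[0] == -1.0
        assert np.isnan(out.data["s1"].tolist()[1])
        assert out.data["s1"].tolist()[2] == 1.0

    def test_empty_sample_rejected(self):
        m = qm({"a": [1.0, np.nan], "b": [2.0, np.nan]}, ["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            normalize_median_center(m)


class TestCompletenessFilter:
    def test_min_per_group_rule(self, two_group_design):
        cols = two_group_design.sample_ids  # 3 case, 3 control
        m = qm({
            "keep": [1, 2, np.nan, 1, 2, 3],
            "drop": [1, np.nan, np.nan, 1, 2, 3],
        }, cols)
        out = filter_by_completeness(m, two_group_design, min_per_group=2)
        assert out.feature_ids == ["keep"]

    def test_min_one_keeps_fully_observed(self, two_group_design, small_matrix):
        out = filter_by_completeness(small_matrix, two_group_design, 1)
        assert out.feature_ids == small_matrix.feature_ids

    def test_idempotent_and_subset(self, two_group_design):
        cols = two_group_design.sample_ids
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(size=(30, 6)), columns=cols,
                            index=[f"f{i}" for i in range(30)])
        data[data > 1.0] = np.nan
        m = QuantMatrix(data)
        once = filter_by_completeness(m, two_group_design, 2)
        twice = filter_by_completeness(once, two_group_design, 2)
        assert set(once.feature_ids) <= set(m.feature_ids)
        assert once.feature_ids == twice.feature_ids


class TestRatios:
    def test_reference_median_subtracted(self, two_group_design):
        cols = two_group_design.sample_ids
        m = qm({"f": [5.0, 4.0, 4.0, 2.0, 4.0, 6.0]}, cols)  # ref median 4
        out = make_log2_ratios_vs_reference(m, two_group_design, "control")
        assert out.data.loc["f"].tolist() == [1.0, 0.0, 0.0]

    def test_all_missing_reference_gives_missing_row(self, two_group_design):
        cols = two_group_design.sample_ids
        m = qm({"f": [5.0, 4.0, 3.0, np.nan, np.nan, np.nan]}, cols)
        out = make_log2_ratios_vs_reference(m, two_group_design, "control")
        assert out.data.loc["f"].isna().all()

    def test_commutes_with_per_sample_shift_after_centering(self, two_group_design,
                                                            small_matrix):
        """Centering then ratios is invariant to adding per-sample constants."""
        shifted = QuantMatrix(small_matrix.data
                              + np.arange(6, dtype=float)[None, :])
        path_a, _ = normalize_median_center(small_matrix)
        path_b, _ = normalize_median_center(shifted)
        ra = make_log2_ratios_vs_reference(path_a, two_group_design, "control")
        rb = make_log2_ratios_vs_reference(path_b, two_group_design, "control")
        np.testing.assert_allclose(ra.data.to_numpy(), rb.data.to_numpy(),
                                   atol=1e-12)


class TestRowScaling:
    def test_mean_zero_sd_one(self):
        m = qm({"f": [1.0, 2.0, 3.0]}, ["a", "b", "c"])
        out = scale_rows_z(m)
        assert out.data.loc["f"].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_row_dropped(self):
        m = qm({"flat": [2.0, 2.0, 2.0], "ok": [0.0, 1.0, 2.0]}, ["a", "b", "c"])
        with pytest.warns(UserWarning):
            out = scale_rows_z(m)
        assert out.feature_ids == ["ok"]

    def test_idempotent(self, small_matrix):
        once = scale_rows_z(small_matrix)
        twice = scale_rows_z(once)
        np.testing.assert_allclose(once.data.to_numpy(), twice.data.to_numpy(),
                                   atol=1e-12)


class TestPCA:
    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(10, 4)),
                            index=[f"f{i}" for i in range(10)],
                            columns=list("abcd"))
        res = run_pca(QuantMatrix(data))
        X = data.to_numpy().T
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(res.explained_variance,
                                   eigvals[: len(res.explained_variance)],
                                   atol=1e-10)

    def test_variance_conservation(self, small_matrix):
        res = run_pca(small_matrix)
        X = small_matrix.data.to_numpy().T
        total = ((X - X.mean(axis=0)) ** 2).sum() / (X.shape[0] - 1)
        assert abs(res.explained_variance.sum() - total) < 1e-9

    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=8)
        data = pd.DataFrame({"s1": base, "s2": base, "s3": rng.normal(size=8)},
                            index=[f"f{i}" for i in range(8)])
        res = run_pca(QuantMatrix(data))
        np.testing.assert_allclose(res.scores.loc["s1"], res.scores.loc["s2"],
                                   atol=1e-10)

    def test_incomplete_rows_excluded(self):
        data = pd.DataFrame({"s1": [1.0, np.nan, 2.0], "s2": [2.0, 1.0, 3.0],
                             "s3": [0.0, 0.0, 1.0]}, index=["a", "b", "c"])
        res = run_pca(QuantMatrix(data))
        assert res.n_features_used == 2 and res.n_features_dropped == 1

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            run_pca(qm({"f": [1.0]}, ["s1"]))


class TestHierarchicalClustering:
    def test_canberra_hand_value(self):
        # canberra([1,2],[2,2]) = |1-2|/(1+2) + 0 = 1/3
        m = qm({"r1": [1.0, 2.0], "r2": [2.0, 2.0]}, ["s1", "s2"])
        res = hierarchical_cluster(m, col_metric="canberra")
        assert res.row_linkage[0, 2] == pytest.approx(1.0 / 3.0)

    def test_identical_columns_zero_pearson_distance(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=6)
        data = pd.DataFrame({"s1": col, "s2": col, "s3": rng.normal(size=6)},
                            index=[f"f{i}" for i in range(6)])
        res = hierarchical_cluster(QuantMatrix(data))
        assert res.col_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_column_rejected_under_pearson(self):
        data = pd.DataFrame({"s1": [1.0, 1.0, 1.0], "s2": [1.0, 2.0, 3.0],
                             "s3": [2.0, 1.0, 0.0]}, index=["a", "b", "c"])
        with pytest.raises(ValueError, match="zero-variance"):
            hierarchical_cluster(QuantMatrix(data))

    def test_matches_exhaustive_agglomeration_oracle(self):
        rng = np.random.default_rng(11)
        data = pd.DataFrame(rng.uniform(1, 5, size=(4, 5)),
                            index=list("wxyz"),
                            columns=[f"s{i}" for i in range(5)])
        res = hierarchical_cluster(QuantMatrix(data), row_metric="canberra")
        # rebuild the oracle's merge list from the same distance matrix
        from scipy.spatial.distance import pdist
        dist = squareform(pdist(data.to_numpy(), metric="canberra"))
        expected = average_linkage_merges(dist)
        # translate scipy linkage into (member set, height) merges
        members = {i: frozenset([i]) for i in range(4)}
        got = []
        for step, (a, b, height, _) in enumerate(res.row_linkage):
            merged = members[int(a)] | members[int(b)]
            members[4 + step] = merged
            got.append((merged, height))
        for (set_e, h_e), (set_g, h_g) in zip(expected, got):
            assert set_e == set_g
            assert h_g == pytest.approx(h_e)

    def test_missing_values_rejected(self):
        m = qm({"a": [1.0, np.nan], "b": [2.0, 3.0], "c": [0.0, 1.0]},
               ["s1", "s2"])
        with pytest.raises(ValueError, match="missing"):
            hierarchical_cluster(m)
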