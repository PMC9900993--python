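"""Expression filters, iFOT normalisation, rank DE, normality check, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import apalink as al
from apalink._stats import bh_fdr, rank_sum_test
from apalink.omics import (differential_test, filter_detected_proteins,
                           filter_expressed_transcripts, normality_check,
                           normalize_ifot, pca_embed)


def matrix(data, unit, samples=None):
    df = pd.DataFrame(data).T if isinstance(data, dict) else pd.DataFrame(data)
    if samples is not None:
        df.columns = samples
    return al.AbundanceMatrix(df, unit=unit)


class TestExpressionFilter:
    def test_boundary_at_the_fpkm_floor(self):
        m = matrix({"below": [0.9, 0.5], "at": [1.0, 0.2], "above": [3.0, 0.1]}, "FPKM")
        kept = filter_expressed_transcripts(m)
        assert list(kept.values.index) == ["at", "above"]

    def test_all_passing_rows_is_identity(self):
        m = matrix({"a": [2.0, 3.0], "b": [5.0, 1.0]}, "FPKM")
        pd.testing.assert_frame_equal(filter_expressed_transcripts(m).values, m.values)

    def test_wrong_unit_rejected(self):
        with pytest.raises(ValueError, match="FPKM"):
            filter_expressed_transcripts(matrix({"a": [2.0]}, "iBAQ"))


class TestIFOT:
    def test_fraction_of_total_times_scale(self):
        m = matrix({"g1": [1.0], "g2": [3.0]}, "iBAQ")
        out = normalize_ifot(m)
        assert out.unit == "iFOT"
        np.testing.assert_allclose(out.values.iloc[:, 0], [25000.0, 75000.0])

    def test_fot_columns_sum_to_one(self):
        rng = np.random.default_rng(1)
        m = matrix(rng.lognormal(0, 1, (20, 6)), "iBAQ")
        fot = normalize_ifot(m).values / 1e5
        np.testing.assert_allclose(fot.sum(axis=0), np.ones(6), rtol=1e-12)

    def test_missing_cells_stay_missing_and_do_not_contribute(self):
        m = matrix({"g1": [1.0], "g2": [np.nan], "g3": [3.0]}, "iBAQ")
        out = normalize_ifot(m)
        assert np.isnan(out.values.loc["g2"].iloc[0])
        np.testing.assert_allclose(out.values.loc[["g1", "g3"]].iloc[:, 0],
                                   [25000.0, 75000.0])

    def test_all_missing_sample_rejected(self):
        m = matrix(np.array([[1.0, np.nan], [2.0, np.nan]]), "iBAQ")
        with pytest.raises(ValueError, match="no detected protein"):
            normalize_ifot(m)


class TestDetectionFilter:
    def test_one_tenth_rounds_up(self):
        # 75 samples: need ceil(7.5) = 8 detections
        vals = np.full((2, 75), np.nan)
        vals[0, :7] = 1.0
        vals[1, :8] = 1.0
        m = al.AbundanceMatrix(pd.DataFrame(vals, index=["seven", "eight"]), unit="iFOT")
        kept = filter_detected_proteins(m)
        assert list(kept.values.index) == ["eight"]

    def test_zero_fraction_is_identity(self):
        m = matrix({"a": [np.nan, np.nan]}, "iFOT")
        assert len(filter_detected_proteins(m, min_fraction=0.0).values) == 1


class TestDifferentialTest:
    def test_complete_separation_small_n_gives_exact_p(self, toy_design):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_median_fold_changes_and_sign_convention(self, toy_design):
        vals = {"up4": [8, 8, 8, 8, 8, 2, 2, 2, 2, 2],
                "down4": [2, 2, 2, 2, 2, 8, 8, 8, 8, 8]}
        m = al.AbundanceMatrix(pd.DataFrame(vals, index=toy_design.samples).T, unit="iFOT")
        t = differential_test(m, toy_design)
        assert t.loc["up4", "fc_linear"] == pytest.approx(4.0)
        assert t.loc["up4", "fc_signed"] == pytest.approx(4.0)
        assert t.loc["down4", "fc_linear"] == pytest.approx(0.25)
        assert t.loc["down4", "fc_signed"] == pytest.approx(-4.0)

    def test_fdr_never_below_p(self, toy_design):
        rng = np.random.default_rng(2)
        m = al.AbundanceMatrix(
            pd.DataFrame(rng.lognormal(0, 1, (40, 10)),
                         index=[f"g{i}" for i in range(40)],
                         columns=toy_design.samples), unit="iFOT")
        t = differential_test(m, toy_design)
        ok = t["p_value"].notna()
        assert (t.loc[ok, "fdr"] >= t.loc[ok, "p_value"] - 1e-12).all()

    def test_group_swap_negates_signed_fold_change(self, toy_design):
        rng = np.random.default_rng(3)
        m = al.AbundanceMatrix(
            pd.DataFrame(rng.lognormal(0, 1, (20, 10)),
                         index=[f"g{i}" for i in range(20)],
                         columns=toy_design.samples), unit="iFOT")
        swapped = al.GroupDesign(toy_design.groups.map(
            {"case": "control", "control": "case"}))
        a = differential_test(m, toy_design)
        b = differential_test(m, swapped)
        ratio_ne_1 = ~np.isclose(a["fc_linear"], 1.0)
        np.testing.assert_allclose(a.loc[ratio_ne_1, "fc_signed"],
                                   -b.loc[ratio_ne_1, "fc_signed"], rtol=1e-9)

    def test_too_few_values_not_testable(self, toy_design):
        vals = [[1.0, np.nan, np.nan, np.nan, np.nan, 2.0, 2.0, 2.0, 2.0, 2.0]]
        m = al.AbundanceMatrix(pd.DataFrame(vals, index=["g"],
                                            columns=toy_design.samples), unit="iFOT")
        assert differential_test(m, toy_design).loc["g", "status"] == "not_testable"


class TestBH:
    @staticmethod
    def naive_bh(p):
        """Independent textbook step-up implementation."""
        p = np.asarray(p, float)
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        prev = 1.0
        for rank_idx in range(n - 1, -1, -1):
            i = order[rank_idx]
            prev = min(prev, p[i] * n / (rank_idx + 1))
            adj[i] = prev
        return adj

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    def test_matches_textbook_step_up_and_dominates_p(self, pvals):
        out = bh_fdr(pvals)
        np.testing.assert_allclose(out, self.naive_bh(pvals), rtol=1e-9, atol=1e-12)
        assert (out >= np.asarray(pvals) - 1e-12).all()

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), rtol=1e-12)


class TestNormalityCheck:
    def test_constant_and_short_vectors_give_missing(self, toy_design):
        vals = {"const": [5.0] * 10,
                "short": [1.0, 2.0, np.nan, np.nan, np.nan, 1, 2, 3, 4, 5],
                "ok": [1.1, 2.3, 3.7, 1.9, 2.8, 1, 2, 3, 4, 5]}
        m = al.AbundanceMatrix(pd.DataFrame(vals, index=toy_design.samples).T, unit="iFOT")
        t = normality_check(m, toy_design)
        assert np.isnan(t.loc["const", "shapiro_p_case"])
        assert np.isnan(t.loc["short", "shapiro_p_case"])
        assert 0 <= t.loc["ok", "shapiro_p_case"] <= 1

    def test_null_pvalues_are_uniform(self):
        # under normal data, Shapiro-Wilk p is U(0,1); KS over seeds
        from scipy import stats

        rng = np.random.default_rng(7)
        ps = [stats.shapiro(rng.normal(size=50)).pvalue for _ in range(200)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPCA:
    def test_two_cluster_structure_separates_on_pc1(self):
        a = np.tile([[10.0], [1.0], [5.0]], (1, 4))
        b = np.tile([[1.0], [10.0], [5.0]], (1, 4))
        m = al.AbundanceMatrix(pd.DataFrame(np.hstack([a, b]),
                                            index=["g1", "g2", "g3"],
                                            columns=[f"s{i}" for i in range(8)]),
                               unit="iFOT")
        coords, explained = pca_embed(m, k=2)
        pc1 = coords["PC1"].to_numpy()
        assert np.allclose(pc1[:4], pc1[0]) and np.allclose(pc1[4:], pc1[4])
        assert not np.isclose(pc1[0], pc1[4])
        assert coords.mean(axis=0).abs().max() < 1e-9
        assert explained[0] >= explained[-1]

    def test_requires_enough_samples(self):
        m = al.AbundanceMatrix(pd.DataFrame([[1.0, 2.0]], index=["g"]), unit="iFOT")
        with pytest.raises(ValueError, match="samples"):
            pca_embed(m, k=2)
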