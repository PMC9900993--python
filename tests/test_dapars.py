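"""Two-isoform change-point fitting and PDUI event calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import apalink as al
from apalink.dapars import (call_apa_events, compute_pdui, default_search,
                            fit_joint_breakpoint, fit_segment_means)
from conftest import step_profile


def brute_force_breakpoint(profiles: dict, candidates) -> int:
    """Independent oracle: naive per-candidate segment means and residuals."""
    best_bp, best_rss = None, np.inf
    for b in candidates:
        total = 0.0
        for d in profiles.values():
            d = np.asarray(d, float)
            m1, m2 = d[:b].mean(), d[b:].mean()
            if m1 >= m2:
                pred = np.where(np.arange(d.size) < b, m1, m2)
            else:
                pred = np.full(d.size, d.mean())
            total += float(((d - pred) ** 2).sum())
        if total < best_rss:
            best_rss, best_bp = total, int(b)
    return best_bp


class TestSegmentMeans:
    def test_exact_step_recovers_abundances_with_zero_residual(self):
        fit = fit_segment_means(step_profile(300, 120, 10, 4), 120)
        assert (fit.alpha, fit.beta, fit.rss) == (4.0, 6.0, 0.0)
        assert not fit.degenerate

    def test_flat_profile_is_pure_long_isoform(self):
        fit = fit_segment_means(np.full(200, 30.0), 77)
        assert (fit.alpha, fit.beta, fit.rss) == (30.0, 0.0, 0.0)

    def test_rising_profile_clamps_short_isoform_to_zero(self):
        fit = fit_segment_means(step_profile(200, 100, 5, 15), 100)
        assert fit.beta == 0.0
        assert fit.alpha == 10.0
        assert fit.degenerate

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError, match="empty segment"):
            fit_segment_means(np.ones(10), 0)


class TestJointBreakpoint:
    def test_shared_noiseless_step_found_exactly(self):
        profiles = {"a": step_profile(400, 150, 60, 20),
                    "b": step_profile(400, 150, 80, 50)}
        fit = fit_joint_breakpoint(profiles)
        assert fit.breakpoint == 150
        assert fit.rss == pytest.approx(0.0, abs=1e-8)

    def test_flat_sample_does_not_move_the_breakpoint(self):
        # a flat profile's residual is breakpoint-invariant, so the stepped
        # sample decides
        profiles = {"flat": np.full(400, 70.0),
                    "step": step_profile(400, 210, 90, 30)}
        assert fit_joint_breakpoint(profiles).breakpoint == 210

    def test_low_coverage_gene_not_fitted(self):
        profiles = {"a": np.full(300, 5.0), "b": np.full(300, 40.0)}
        fit = fit_joint_breakpoint(profiles, min_coverage=30.0)
        assert fit.qc_flag == "low_coverage"
        assert fit.breakpoint is None

    def test_grid_equals_brute_force_on_noisy_profiles(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            L = int(rng.integers(200, 500))
            bp_true = int(rng.integers(60, L - 60))
            profiles = {
                s: rng.poisson(step_profile(L, bp_true, 50, 50 * rng.uniform(0.1, 0.9))
                               ).astype(float)
                for s in ("s1", "s2", "s3")
            }
            candidates = default_search(L)
            fit = fit_joint_breakpoint(profiles)
            assert fit.breakpoint == brute_force_breakpoint(profiles, candidates)


class TestPDUI:
    @pytest.mark.parametrize("alpha,beta,expected", [
        (5.0, 5.0, 0.5), (0.0, 7.0, 0.0), (4.0, 6.0, 0.4), (3.0, 0.0, 1.0)])
    def test_ratio(self, alpha, beta, expected):
        assert compute_pdui(alpha, beta) == pytest.approx(expected)

    def test_zero_total_is_missing(self):
        assert np.isnan(compute_pdui(0.0, 0.0))

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            compute_pdui(-1.0, 2.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_always_within_unit_interval(self, alpha, beta):
        p = compute_pdui(alpha, beta)
        assert np.isnan(p) or 0.0 <= p <= 1.0


def _usage_frame(case_vals, ctrl_vals, design):
    row = list(case_vals) + list(ctrl_vals)
    return pd.DataFrame([row], index=pd.Index(["G"], name="gene_id"),
                        columns=design.samples)


class TestEventCalling:
    def test_large_shift_with_small_p_is_lengthened(self, toy_design):
        usage = _usage_frame([0.78, 0.80, 0.82, 0.79, 0.81],
                             [0.58, 0.60, 0.62, 0.59, 0.61], toy_design)
        row = call_apa_events(usage, toy_design).iloc[0]
        assert row["delta"] == pytest.approx(0.2)
        assert row["p_value"] <= 0.05
        assert row["class"] == "lengthened"

    def test_small_shift_fails_delta_cut_despite_significance(self, toy_design):
        usage = _usage_frame([0.65, 0.651, 0.652, 0.653, 0.654],
                             [0.60, 0.601, 0.602, 0.603, 0.604], toy_design)
        row = call_apa_events(usage, toy_design).iloc[0]
        assert row["p_value"] <= 0.01
        assert row["class"] == "unchanged"

    def test_large_shift_fails_p_cut(self, toy_design):
        usage = _usage_frame([0.2, 0.9, 0.1, 0.85, 0.3],
                             [0.6, 0.58, 0.95, 0.05, 0.5], toy_design)
        row = call_apa_events(usage, toy_design).iloc[0]
        if abs(row["delta"]) > 0.1:  # medians happen to differ; p must gate
            assert row["p_value"] > 0.05
        assert row["class"] == "unchanged"

    def test_insufficient_samples_is_not_testable(self, toy_design):
        usage = _usage_frame([0.8, 0.8, np.nan, np.nan, np.nan],
                             [0.6, 0.6, 0.6, 0.6, 0.6], toy_design)
        assert call_apa_events(usage, toy_design).iloc[0]["class"] == "not_testable"

    def test_unknown_design_sample_rejected(self, toy_design):
        usage = _usage_frame([0.8] * 5, [0.6] * 5, toy_design)
        with pytest.raises(ValueError, match="absent"):
            call_apa_events(usage.drop(columns=["case_0"]), toy_design)

    def test_label_swap_negates_delta_and_keeps_p(self, toy_design):
        rng = np.random.default_rng(5)
        usage = pd.DataFrame(rng.uniform(0, 1, (20, 10)),
                             index=pd.Index([f"g{i}" for i in range(20)], name="gene_id"),
                             columns=toy_design.samples)
        swapped = al.GroupDesign(toy_design.groups.map(
            {"case": "control", "control": "case"}))
        a = call_apa_events(usage, toy_design)
        b = call_apa_events(usage, swapped)
        np.testing.assert_allclose(a["delta"], -b["delta"], atol=1e-12)
        np.testing.assert_allclose(a["p_value"], b["p_value"], atol=1e-12)


class TestCoverageAPAModel:
    def test_breakpoints_match_planted_sites(self, recovery_cohort, recovery_apa):
        truth = recovery_cohort.truth
        bp = recovery_apa.table["breakpoint"]
        fitted = bp.dropna()
        err = (fitted - truth.loc[fitted.index, "proximal_pos"]).abs()
        assert (err <= 5).mean() >= 0.95

    def test_summary_reports_counts(self, recovery_apa):
        text = recovery_apa.summary()
        assert "lengthened" in text and "PDUI" in text

    def test_table_export(self, recovery_apa, tmp_path):
        path = recovery_apa.to_tsv(tmp_path / "calls.tsv")
        df = pd.read_csv(path, sep="\t", comment="#")
        assert "delta" in df.columns and len(df) == len(recovery_apa.table)
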