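"""Synthetic-cohort generator: planted structure, determinism, round trips."""

import dataclasses
import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import apalink as al
from apalink.simulate import ConfigError, SimConfig, simulate_utr_coverage, write_cohort


class TestConfig:
    @pytest.mark.parametrize("field,value,match", [
        ("frac_lengthened", 1.2, "frac_lengthened"),
        ("utr_len_range", (100, 500), "utr_len_range"),
        ("mean_depth", 0.0, "mean_depth"),
        ("n_enhancer_rbps", 99, "n_enhancer_rbps"),
        ("noise_model", "gauss", "noise_model"),
        ("detection_dropout", -0.1, "detection_dropout"),
    ])
    def test_invalid_config_names_the_field(self, field, value, match):
        kwargs = {field: value}
        with pytest.raises(ConfigError, match=match):
            SimConfig(**kwargs)

    def test_fraction_sum_constraint(self):
        with pytest.raises(ConfigError, match="<= 1"):
            SimConfig(frac_lengthened=0.7, frac_shortened=0.5)


class TestPlantedStructure:
    def test_class_counts_round_the_stated_fractions(self):
        cfg = SimConfig(n_genes=100, n_case=3, n_control=3,
                        frac_lengthened=0.3, frac_shortened=0.02, seed=1)
        counts = al.generate_cohort(cfg).truth["class"].value_counts()
        assert counts["lengthened"] == 30
        assert counts["shortened"] == 2
        assert counts["unchanged"] == 68

    def test_planted_shift_respects_configured_minimum(self, small_cohort):
        t = small_cohort.truth
        lng = t[t["class"] == "lengthened"]
        delta_min = small_cohort.config.delta_pdui_range[0]
        assert ((lng["pdui_case"] - lng["pdui_control"]) >= delta_min - 1e-12).all()
        assert t["pdui_case"].between(0, 1).all()
        assert (t["proximal_pos"] > 0).all()
        assert (t["proximal_pos"] < t["utr_length"]).all()

    def test_same_seed_reproduces_the_truth_table(self):
        cfg = SimConfig(n_genes=50, n_case=3, n_control=3, seed=7)
        a = al.generate_cohort(cfg)
        b = al.generate_cohort(dataclasses.replace(cfg))
        pd.testing.assert_frame_equal(a.truth, b.truth)
        g = a.truth.index[0]
        s = a.design.samples[0]
        assert np.array_equal(a.coverage[g][s], b.coverage[g][s])

    def test_enhancer_rbp_count_matches_config(self, small_cohort):
        assert small_cohort.rbp_truth["is_enhancer"].sum() == \
            small_cohort.config.n_enhancer_rbps

    def test_gained_site_bookkeeping_matches_interval_overlap(self, small_cohort):
        c = small_cohort
        enh = set(c.rbp_truth.loc[c.rbp_truth["is_enhancer"], "rbp"])
        sites = c.rbp_sites.sites
        for _, g in c.truth.iterrows():
            if g["class"] != "lengthened":
                assert g["translation_boost_log2"] == 0.0
                continue
            sub = sites[(sites["gene_id"] == g["gene_id"]) & sites["rbp"].isin(enh)]
            expected = int((sub["end"] > g["proximal_pos"]).sum())
            assert g["enhancer_sites_gained"] == expected
            assert g["translation_boost_log2"] == pytest.approx(
                c.config.enhancer_boost_log2 * expected)


class TestCoverageModel:
    def test_pure_long_isoform_is_flat(self):
        rng = np.random.default_rng(0)
        vec = simulate_utr_coverage(200, 80, 1.0, 30.0, rng, noise_model="none")
        assert np.array_equal(vec, np.full(200, 30.0))

    def test_pure_short_isoform_ends_at_proximal_site(self):
        rng = np.random.default_rng(0)
        vec = simulate_utr_coverage(200, 80, 0.0, 30.0, rng, noise_model="none")
        assert np.array_equal(vec[:80], np.full(80, 30.0))
        assert np.array_equal(vec[80:], np.zeros(120))

    def test_mixture_steps_at_proximal_site(self):
        rng = np.random.default_rng(0)
        vec = simulate_utr_coverage(300, 120, 0.4, 10.0, rng, noise_model="none")
        assert np.allclose(vec[:120], 10.0) and np.allclose(vec[120:], 4.0)

    def test_noiseless_coverage_reproduces_planted_usage(self):
        cfg = SimConfig(n_genes=20, n_case=3, n_control=3, noise_model="none", seed=2)
        c = al.generate_cohort(cfg)
        for g, row in c.truth.iterrows():
            prox = int(row["proximal_pos"])
            for s in c.design.samples:
                vec = c.coverage[g][s]
                pdui = vec[prox] / vec[0]
                assert pdui == pytest.approx(c.sample_pdui.loc[g, s], abs=1e-12)


class TestExpressionModel:
    def test_protein_dropout_rate_matches_config(self, small_cohort):
        frac = small_cohort.protein.values.isna().to_numpy().mean()
        assert frac == pytest.approx(small_cohort.config.detection_dropout, abs=0.02)

    def test_boost_multiplies_protein_but_not_mrna_ratio(self):
        # one gene, huge sample count, tiny noise: ratios approach the model
        cfg = SimConfig(n_genes=40, n_case=50, n_control=50, frac_lengthened=1.0,
                        frac_shortened=0.0, frac_de_mrna=0.0, protein_noise_sd=0.01,
                        mrna_within_sd=0.01, detection_dropout=0.0,
                        enhancer_boost_log2=1.0, seed=3)
        c = al.generate_cohort(cfg)
        case, ctrl = c.design.case_samples, c.design.control_samples
        for g, row in c.truth.iterrows():
            mrna_ratio = (c.mrna.values.loc[g, case].median()
                          / c.mrna.values.loc[g, ctrl].median())
            prot_ratio = (c.protein.values.loc[g, case].median()
                          / c.protein.values.loc[g, ctrl].median())
            assert mrna_ratio == pytest.approx(1.0, rel=0.05)
            assert prot_ratio == pytest.approx(2 ** row["translation_boost_log2"], rel=0.1)


class TestWriteCohort:
    def test_manifest_and_round_trips(self, small_cohort, tmp_path):
        c = small_cohort
        manifest = write_cohort(c, tmp_path / "cohort")
        n_samples = len(c.design.samples)
        assert sum(1 for k in manifest if k.startswith("coverage:")) == n_samples
        ann = al.read_utr_annotation(manifest["annotation"])
        assert set(ann) == set(c.annotation)
        s = c.design.samples[0]
        cov = al.read_bedgraph_coverage(manifest[f"coverage:{s}"], ann)
        for g in c.coverage:
            assert np.array_equal(cov[g], c.coverage[g][s])
        mrna = al.read_matrix(manifest["mrna"])
        assert mrna.unit == "FPKM"
        np.testing.assert_allclose(mrna.values.to_numpy(),
                                   c.mrna.values.to_numpy(), rtol=1e-9)
        sites = al.RBPSiteSet.from_bed6(manifest["rbp_sites"])
        assert len(sites.sites) == len(c.rbp_sites.sites)

    def test_same_seed_writes_byte_identical_files(self, tmp_path):
        cfg = SimConfig(n_genes=30, n_case=3, n_control=3, seed=9)
        m1 = write_cohort(al.generate_cohort(cfg), tmp_path / "a")
        m2 = write_cohort(al.generate_cohort(SimConfig(n_genes=30, n_case=3,
                                                       n_control=3, seed=9)),
                          tmp_path / "b")
        for key in m1:
            if key == "manifest":
                continue
            assert filecmp.cmp(m1[key], m2[key], shallow=False), key
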