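"""Shared fixtures: small seeded cohorts and the full default study.

Cohorts are generated once per session; everything downstream (APA calls, DE
tables, integration, RBP screen) is derived lazily and cached so acceptance
and unit tests can share the heavy objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import apalink as al
from apalink import omics


@pytest.fixture(scope="session")
def small_cohort():
    """100 genes, 5 vs 5 — fast fixture for I/O and bookkeeping tests."""
    cfg = al.SimConfig(n_genes=100, n_case=5, n_control=5, utr_len_range=(300, 800), seed=42)
    return al.generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_cohort():
    """The planted-event recovery study: 500 genes, 10 vs 10, 50x depth,
    usage shifts of 0.25-0.5."""
    cfg = al.SimConfig(n_genes=500, n_case=10, n_control=10, seed=11)
    return al.generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_apa(recovery_cohort):
    c = recovery_cohort
    return al.CoverageAPA(c.coverage, c.annotation, c.design).fit()


@pytest.fixture(scope="session")
def recovery_qapa(recovery_cohort):
    c = recovery_cohort
    return al.IsoformAPA(c.isoform_quant, c.design).fit()


@pytest.fixture(scope="session")
def default_cohort():
    """The boosted default study (2000 genes, default seed), samples scaled
    to 10 vs 10."""
    cfg = al.SimConfig(n_case=10, n_control=10, seed=0)
    return al.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """Full downstream analysis of the default cohort, computed once."""
    c = default_cohort
    apa = al.CoverageAPA(c.coverage, c.annotation, c.design).fit()
    mrna_de = al.WilcoxonDE(omics.filter_expressed_transcripts(c.mrna), c.design).fit()
    protein_ifot = omics.filter_detected_proteins(omics.normalize_ifot(c.protein))
    protein_de = al.WilcoxonDE(protein_ifot, c.design).fit()
    integ = al.ProteogenomicsIntegration(
        mrna_de.table, protein_de.table, apa_table=apa.table,
        usage=apa.usage, protein_values=protein_ifot.values).fit()
    rbp = al.RBPGainAnalysis(apa.table, c.annotation, c.rbp_sites,
                             integ.fc_ratio).fit()
    return {"cohort": c, "apa": apa, "mrna_de": mrna_de, "protein_de": protein_de,
            "protein_ifot": protein_ifot, "integration": integ, "rbp": rbp}


@pytest.fixture()
def toy_design():
    return al.GroupDesign(pd.Series(
        ["case"] * 5 + ["control"] * 5,
        index=[f"case_{i}" for i in range(5)] + [f"ctrl_{i}" for i in range(5)]))


def step_profile(length: int, breakpoint: int, proximal: float, distal: float) -> np.ndarray:
    vec = np.full(length, float(distal))
    vec[:breakpoint] = proximal
    return vec
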