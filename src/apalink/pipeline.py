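"""End-to-end orchestration: simulate (optional) -> coverage APA -> isoform
APA -> DE (mRNA, protein) -> integration -> RBP gain screen.

Each stage writes its outputs before the next starts; a machine-readable
``summary.json`` collects counts and all effective parameters.  Reruns with
the same config reproduce identical files (headers carry a config hash, never
a timestamp).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, io, omics
from .dapars import CoverageAPA
from .integrate import ProteogenomicsIntegration
from .qapa import IsoformAPA, concordance
from .rbp import RBPGainAnalysis
from .simulate import SimConfig, generate_cohort, write_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, stage toggles and the published default thresholds.

    When ``simulate`` is true the input paths are generated under
    ``out_dir/cohort`` first; otherwise annotation/coverage/quant/matrix
    paths must point at existing files.
    """

    out_dir: str = "apalink_out"
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    annotation: str | None = None
    coverage_dir: str | None = None
    isoform_quant: str | None = None
    mrna: str | None = None
    protein: str | None = None
    rbp_sites: str | None = None
    design: str | None = None

    run_dapars: bool = True
    run_qapa: bool = True
    run_de: bool = True
    run_integration: bool = True
    run_rbp: bool = True

    delta_pdui_cut: float = 0.1
    delta_dpau_cut: float = 10.0
    apa_p_cut: float = 0.05
    min_coverage: float = 30.0
    fc_cut: float = 2.0
    fdr_cut: float = 0.01
    fpkm_floor: float = 1.0
    detection_fraction: float = 0.1
    ifot_scale: float = 1e5
    min_per_group: int = 3
    min_bound: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name: str):
    log.info("stage %s", name)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the summary dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": cfg.seed,
                     "parameters": {k: v for k, v in dataclasses.asdict(cfg).items()
                                    if k not in ("sim",)}}

    if cfg.simulate:
        _stage("simulate")
        sim_cfg = SimConfig(**{"seed": cfg.seed, **cfg.sim})
        cohort = generate_cohort(sim_cfg)
        write_cohort(cohort, out / "cohort")
        annotation = cohort.annotation
        coverage = cohort.coverage
        quant = cohort.isoform_quant
        mrna_raw, protein_raw = cohort.mrna, cohort.protein
        sites = cohort.rbp_sites
        design = cohort.design
        summary["simulate"] = {"n_genes": sim_cfg.n_genes,
                               "n_case": sim_cfg.n_case, "n_control": sim_cfg.n_control,
                               "config_hash": sim_cfg.config_hash()}
    else:
        _stage("load")
        annotation = io.read_utr_annotation(cfg.annotation)
        design = io.GroupDesign.from_tsv(cfg.design)
        coverage = None
        if cfg.run_dapars:
            if not cfg.coverage_dir:
                raise ValueError("stage dapars: coverage_dir is required")
            coverage = {}
            for s in design.samples:
                path = Path(cfg.coverage_dir) / f"{s}.bedgraph"
                per = io.read_bedgraph_coverage(path, annotation)
                for g, vec in per.items():
                    coverage.setdefault(g, {})[s] = vec
        quant = io.read_isoform_quant(cfg.isoform_quant) if cfg.isoform_quant else None
        mrna_raw = io.read_matrix(cfg.mrna, unit="FPKM") if cfg.mrna else None
        protein_raw = io.read_matrix(cfg.protein, unit="iBAQ") if cfg.protein else None
        sites = io.RBPSiteSet.from_bed6(cfg.rbp_sites) if cfg.rbp_sites else None

    tag = f"apalink v{__version__} seed={cfg.seed}"
    apa_res = None
    if cfg.run_dapars:
        _stage("dapars")
        apa_res = CoverageAPA(coverage, annotation, design,
                              delta_cut=cfg.delta_pdui_cut, p_cut=cfg.apa_p_cut,
                              min_coverage=cfg.min_coverage,
                              min_per_group=cfg.min_per_group).fit()
        apa_res.to_tsv(out / "dapars_calls.tsv", header=tag)
        summary["dapars"] = apa_res.counts

    qapa_res = None
    if cfg.run_qapa and quant is not None:
        _stage("qapa")
        qapa_res = IsoformAPA(quant, design, delta_cut=cfg.delta_dpau_cut,
                              p_cut=cfg.apa_p_cut,
                              min_per_group=cfg.min_per_group).fit()
        qapa_res.to_tsv(out / "qapa_calls.tsv", header=tag)
        summary["qapa"] = qapa_res.counts
        if apa_res is not None:
            conc = concordance(apa_res.table, qapa_res.table)
            summary["qapa"]["fraction_lengthened_concordant"] = \
                conc["fraction_lengthened_concordant"]

    mrna_de = protein_de = None
    protein_ifot = None
    if cfg.run_de and mrna_raw is not None and protein_raw is not None:
        _stage("de")
        mrna = omics.filter_expressed_transcripts(mrna_raw, min_max_fpkm=cfg.fpkm_floor)
        mrna_de = omics.WilcoxonDE(mrna, design, fc_cut=cfg.fc_cut, fdr_cut=cfg.fdr_cut,
                                   min_per_group=cfg.min_per_group).fit()
        mrna_de.to_tsv(out / "de_mrna.tsv", header=tag)
        protein_ifot = omics.filter_detected_proteins(
            omics.normalize_ifot(protein_raw, scale=cfg.ifot_scale),
            min_fraction=cfg.detection_fraction)
        protein_de = omics.WilcoxonDE(protein_ifot, design, fc_cut=cfg.fc_cut,
                                      fdr_cut=cfg.fdr_cut,
                                      min_per_group=cfg.min_per_group).fit()
        protein_de.to_tsv(out / "de_protein.tsv", header=tag)
        summary["de"] = {"mrna": mrna_de.counts, "protein": protein_de.counts}

    integ = None
    if cfg.run_integration and mrna_de is not None and protein_de is not None:
        _stage("integrate")
        integ = ProteogenomicsIntegration(
            mrna_de.table, protein_de.table,
            apa_table=apa_res.table if apa_res is not None else None,
            usage=apa_res.usage if apa_res is not None else None,
            protein_values=protein_ifot.values,
            usage_metric="PDUI").fit()
        io.write_table(integ.fc_ratio.reset_index(), out / "fc_ratio.tsv", header=tag)
        if integ.crosstab is not None:
            io.write_table(integ.crosstab, out / "crosstab.tsv", header=tag)
        if integ.correlation is not None:
            io.write_table(integ.correlation.reset_index(),
                           out / "usage_protein_corr.tsv", header=tag)
        summary["integration"] = {"fc_ratio": integ.fc_summary,
                                  "group_test": integ.group_test,
                                  "correlation": integ.correlation_summary}

    if cfg.run_rbp and integ is not None and sites is not None and apa_res is not None:
        _stage("rbp")
        rbp_res = RBPGainAnalysis(apa_res.table, annotation, sites, integ.fc_ratio,
                                  min_bound=cfg.min_bound, p_cut=cfg.apa_p_cut).fit()
        io.write_table(rbp_res.gains, out / "gains.tsv", header=tag)
        io.write_table(rbp_res.enrichment.reset_index(),
                       out / "rbp_enrichment.tsv", header=tag)
        summary["rbp"] = {"fraction_with_gain": rbp_res.gain_fraction,
                          "n_enhancer_rbps": len(rbp_res.enhancer_rbps),
                          "enhancer_rbps": rbp_res.enhancer_rbps}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
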