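"""Synthetic two-group cohort generator with planted APA and translation effects.

The generator emulates the statistical structure of a case/control glomerular
proteogenomics study: per-gene 3'UTR coverage follows the two-isoform step
model (a long isoform spanning the UTR plus a short isoform ending at a
proximal poly(A) site), distal usage shifts between groups for a planted set
of lengthened (and a small set of shortened) genes in a roughly 95:5
lengthening:shortening imbalance, mRNA abundance is log-normal with a planted
differential subset, and protein abundance follows mRNA plus a per-gene
translation boost driven by enhancer-RBP sites gained in extended 3'UTRs:

    log2 protein = log2 mRNA + offset_g + boost_g * 1[case] + noise
    boost_g      = enhancer_boost_log2 * (# enhancer-RBP sites in the
                                          extended region), lengthened genes only

Proteome missingness is left-censored: per sample, values below the
``detection_dropout`` quantile are set missing.  Every component is
deterministic under the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .io import (AbundanceMatrix, GroupDesign, RBPSiteSet, UTRAnnotation,
                 write_bedgraph_coverage, write_table, write_utr_annotation)

GENE_CLASSES = ("lengthened", "shortened", "unchanged")


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe the emulated cohort at reduced scale: 2000 genes,
    25 vs 25 samples (tests scale to 10 vs 10), 50x mean UTR depth, 30%
    lengthened vs 2% shortened genes (the ~95:5 imbalance direction), planted
    usage shifts of 0.25-0.5, and a 0.5 log2 translation boost per gained
    enhancer-RBP site.
    """

    n_genes: int = 2000
    n_case: int = 25
    n_control: int = 25
    frac_lengthened: float = 0.30
    frac_shortened: float = 0.02
    utr_len_range: tuple[int, int] = (300, 1500)
    proximal_frac_range: tuple[float, float] = (0.25, 0.75)
    pdui_base_beta: tuple[float, float] = (2.0, 2.0)
    delta_pdui_range: tuple[float, float] = (0.25, 0.50)
    pdui_concentration: float = 60.0  # within-group Beta concentration of per-sample usage
    mean_depth: float = 50.0
    depth_dispersion: float = 0.0  # NB dispersion; 0 -> Poisson
    noise_model: str = "poisson"  # poisson | nb | none
    frac_de_mrna: float = 0.15
    mrna_fc_range: tuple[float, float] = (2.0, 6.0)
    mrna_log2_mean: float = 4.0
    mrna_log2_sd: float = 2.0
    mrna_within_sd: float = 0.5  # log2, within-group
    n_rbps: int = 50
    n_enhancer_rbps: int = 8
    enhancer_boost_log2: float = 0.5  # per gained enhancer site
    enhancer_site_prob: float = 0.25  # per (enhancer RBP, lengthened gene)
    background_site_prob: float = 0.15  # per (RBP, gene), uniform placement
    site_len: int = 10
    protein_offset_sd: float = 1.0  # log2, per-gene protein/mRNA offset
    protein_noise_sd: float = 0.5  # log2, per-measurement
    quant_noise_sd: float = 0.05  # log2 noise on isoform abundances
    detection_dropout: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("frac_lengthened", "frac_shortened", "frac_de_mrna",
                     "detection_dropout", "enhancer_site_prob", "background_site_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.frac_lengthened + self.frac_shortened > 1.0:
            raise ConfigError("frac_lengthened + frac_shortened must be <= 1")
        if self.utr_len_range[0] < 200:
            raise ConfigError("utr_len_range minimum must be >= 200 bp")
        if self.utr_len_range[0] > self.utr_len_range[1]:
            raise ConfigError("utr_len_range must be (min, max) with min <= max")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if self.depth_dispersion < 0:
            raise ConfigError("depth_dispersion must be >= 0")
        if self.n_enhancer_rbps > self.n_rbps:
            raise ConfigError("n_enhancer_rbps must be <= n_rbps")
        if self.noise_model not in ("poisson", "nb", "none"):
            raise ConfigError(f"noise_model must be poisson|nb|none, got {self.noise_model}")
        for name in ("n_genes", "n_case", "n_control", "n_rbps"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        lo, hi = self.proximal_frac_range
        if not 0.0 < lo <= hi < 1.0:
            raise ConfigError("proximal_frac_range must satisfy 0 < min <= max < 1")
        d_lo, d_hi = self.delta_pdui_range
        if not 0.0 < d_lo <= d_hi < 1.0:
            raise ConfigError("delta_pdui_range must satisfy 0 < min <= max < 1")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


@dataclass
class SyntheticCohort:
    """All components of one simulated study, keyed consistently by gene id."""

    config: SimConfig
    annotation: dict[str, UTRAnnotation]
    coverage: dict[str, dict[str, np.ndarray]]  # gene -> sample -> depth vector
    isoform_quant: pd.DataFrame
    mrna: AbundanceMatrix
    protein: AbundanceMatrix
    rbp_sites: RBPSiteSet
    rbp_truth: pd.DataFrame  # rbp, is_enhancer
    truth: pd.DataFrame  # per-gene planted parameters
    sample_pdui: pd.DataFrame  # genes x samples latent distal usage
    design: GroupDesign


# ---------------------------------------------------------------------------
# component simulators
# ---------------------------------------------------------------------------


def simulate_utr_coverage(utr_length: int, proximal_pos: int, sample_pdui: float,
                          depth: float, rng: np.random.Generator,
                          noise_model: str = "poisson",
                          dispersion: float = 0.0) -> np.ndarray:
    """Per-base depth for one gene/sample under the two-isoform step model.

    Expected depth is ``depth`` before the proximal site and
    ``depth * sample_pdui`` after it; counts are Poisson (or gamma-Poisson
    when ``dispersion`` > 0) around the expectation, or exact with
    ``noise_model='none'``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    mu = np.full(utr_length, depth * sample_pdui)
    mu[:proximal_pos] = depth
    if noise_model == "none":
        return mu
    if noise_model == "nb" and dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=np.maximum(mu, 1e-12) * dispersion)
        return rng.poisson(lam).astype(float)
    return rng.poisson(mu).astype(float)


def _plant_usage(cfg: SimConfig, classes: np.ndarray, rng: np.random.Generator):
    """Group-mean distal usage per gene honouring the planted shift."""
    n = len(classes)
    a, b = cfg.pdui_base_beta
    base = rng.beta(a, b, size=n)
    delta = rng.uniform(*cfg.delta_pdui_range, size=n)
    pdui_control = np.empty(n)
    pdui_case = np.empty(n)
    for i, cls in enumerate(classes):
        if cls == "lengthened":
            # control mean squeezed below 1 - delta so the planted shift survives
            lo, hi = 0.02, 1.0 - delta[i] - 0.02
            pdui_control[i] = lo + base[i] * (hi - lo)
            pdui_case[i] = pdui_control[i] + delta[i]
        elif cls == "shortened":
            lo, hi = delta[i] + 0.02, 0.98
            pdui_control[i] = lo + base[i] * (hi - lo)
            pdui_case[i] = pdui_control[i] - delta[i]
        else:
            pdui_control[i] = 0.02 + base[i] * 0.96
            pdui_case[i] = pdui_control[i]
            delta[i] = 0.0
    return pdui_control, np.clip(pdui_case, 0.0, 1.0), delta


def _sample_usage(mean: float, kappa: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Per-sample usage jitter: Beta re-parameterised around the group mean."""
    m = float(np.clip(mean, 0.01, 0.99))
    return rng.beta(m * kappa, (1.0 - m) * kappa, size=size)


def simulate_rbp_sites(truth: pd.DataFrame, cfg: SimConfig,
                       rng: np.random.Generator) -> tuple[RBPSiteSet, pd.DataFrame]:
    """Binding sites: enhancer RBPs target extended regions of lengthened
    genes; all RBPs additionally bind uniformly at a background rate."""
    rbps = [f"RBP{i + 1:02d}" for i in range(cfg.n_rbps)]
    is_enh = np.zeros(cfg.n_rbps, dtype=bool)
    is_enh[:cfg.n_enhancer_rbps] = True
    rows = []
    site_len = cfg.site_len
    for _, g in truth.iterrows():
        L, prox = int(g["utr_length"]), int(g["proximal_pos"])
        for rbp, enh in zip(rbps, is_enh):
            if enh and g["class"] == "lengthened" and rng.random() < cfg.enhancer_site_prob:
                hi = max(prox, L - site_len)
                start = int(rng.integers(prox, hi + 1))
                rows.append((rbp, g["gene_id"], start, min(start + site_len, L)))
            if rng.random() < cfg.background_site_prob:
                start = int(rng.integers(0, max(1, L - site_len)))
                rows.append((rbp, g["gene_id"], start, min(start + site_len, L)))
    sites = RBPSiteSet(pd.DataFrame(rows, columns=["rbp", "gene_id", "start", "end"]))
    rbp_truth = pd.DataFrame({"rbp": rbps, "is_enhancer": is_enh})
    return sites, rbp_truth


def _count_gained(truth: pd.DataFrame, sites: RBPSiteSet, enhancer_rbps: set[str]) -> np.ndarray:
    """Enhancer-RBP sites overlapping each lengthened gene's extended region."""
    out = np.zeros(len(truth), dtype=int)
    enh_sites = sites.sites[sites.sites["rbp"].isin(enhancer_rbps)]
    by_gene = dict(tuple(enh_sites.groupby("gene_id")))
    for i, (_, g) in enumerate(truth.iterrows()):
        if g["class"] != "lengthened":
            continue
        sub = by_gene.get(g["gene_id"])
        if sub is None:
            continue
        out[i] = int((sub["end"] > g["proximal_pos"]).sum())
    return out


def simulate_expression(truth: pd.DataFrame, cfg: SimConfig, design: GroupDesign,
                        rng: np.random.Generator) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """mRNA (FPKM-like) and protein (iBAQ-like) matrices from the truth table.

    mRNA is log-normal per gene with the planted fold change applied to case
    samples; protein couples to mRNA through a per-gene offset plus the
    translation boost in case samples, then loses values below each sample's
    detection quantile.
    """
    samples = design.samples
    is_case = np.array([s in set(design.case_samples) for s in samples])
    n_g, n_s = len(truth), len(samples)
    base = rng.normal(cfg.mrna_log2_mean, cfg.mrna_log2_sd, size=n_g)
    log2_fc = np.log2(truth["mrna_fc_true"].to_numpy(dtype=float))
    noise = rng.normal(0.0, cfg.mrna_within_sd, size=(n_g, n_s))
    log2_mrna = base[:, None] + np.where(is_case[None, :], log2_fc[:, None], 0.0) + noise
    mrna = AbundanceMatrix(
        pd.DataFrame(np.exp2(log2_mrna), index=truth["gene_id"].rename("gene_id"),
                     columns=samples),
        unit="FPKM")

    offset = rng.normal(0.0, cfg.protein_offset_sd, size=n_g)
    boost = truth["translation_boost_log2"].to_numpy(dtype=float)
    p_noise = rng.normal(0.0, cfg.protein_noise_sd, size=(n_g, n_s))
    log2_prot = (log2_mrna + offset[:, None]
                 + np.where(is_case[None, :], boost[:, None], 0.0) + p_noise)
    prot = np.exp2(log2_prot)
    if cfg.detection_dropout > 0:
        cutoffs = np.quantile(prot, cfg.detection_dropout, axis=0)
        prot = np.where(prot < cutoffs[None, :], np.nan, prot)
    protein = AbundanceMatrix(
        pd.DataFrame(prot, index=truth["gene_id"].rename("gene_id"), columns=samples),
        unit="iBAQ")
    return mrna, protein


def _simulate_isoform_quant(truth: pd.DataFrame, sample_pdui: pd.DataFrame,
                            mrna: AbundanceMatrix, cfg: SimConfig,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Two-isoform abundance table consistent with the latent per-sample usage."""
    samples = list(sample_pdui.columns)
    rows = []
    total = mrna.values.reindex(truth["gene_id"]).to_numpy(dtype=float)
    usage = sample_pdui.reindex(truth["gene_id"]).to_numpy(dtype=float)
    noisy = cfg.noise_model != "none" and cfg.quant_noise_sd > 0
    for i, (_, g) in enumerate(truth.iterrows()):
        distal = total[i] * usage[i]
        proximal = total[i] * (1.0 - usage[i])
        if noisy:
            distal = distal * np.exp2(rng.normal(0, cfg.quant_noise_sd, len(samples)))
            proximal = proximal * np.exp2(rng.normal(0, cfg.quant_noise_sd, len(samples)))
        rows.append([g["gene_id"], f"{g['gene_id']}_P", int(g["proximal_pos"]), *proximal])
        rows.append([g["gene_id"], f"{g['gene_id']}_D", int(g["utr_length"]), *distal])
    return pd.DataFrame(rows, columns=["gene_id", "isoform_id", "pas_offset", *samples])


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def generate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic study; deterministic under ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    n_len = round(cfg.frac_lengthened * n)
    n_short = round(cfg.frac_shortened * n)
    classes = np.array(["lengthened"] * n_len + ["shortened"] * n_short
                       + ["unchanged"] * (n - n_len - n_short))
    rng.shuffle(classes)
    gene_ids = [f"G{i + 1:05d}" for i in range(n)]

    utr_length = rng.integers(cfg.utr_len_range[0], cfg.utr_len_range[1] + 1, size=n)
    prox_frac = rng.uniform(*cfg.proximal_frac_range, size=n)
    proximal_pos = np.maximum(1, np.minimum(utr_length - 1,
                                            np.round(utr_length * prox_frac))).astype(int)
    pdui_control, pdui_case, delta = _plant_usage(cfg, classes, rng)

    de_mask = rng.random(n) < cfg.frac_de_mrna
    fc = rng.uniform(*cfg.mrna_fc_range, size=n)
    down = rng.random(n) < 0.5
    mrna_fc_true = np.where(de_mask, np.where(down, 1.0 / fc, fc), 1.0)

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "utr_length": utr_length,
        "proximal_pos": proximal_pos,
        "class": classes,
        "pdui_control": pdui_control,
        "pdui_case": pdui_case,
        "delta_pdui_true": np.where(classes == "shortened", -delta, delta),
        "mrna_de": de_mask,
        "mrna_fc_true": mrna_fc_true,
    })

    sites, rbp_truth = simulate_rbp_sites(truth, cfg, rng)
    enhancer_rbps = set(rbp_truth.loc[rbp_truth["is_enhancer"], "rbp"])
    truth["enhancer_sites_gained"] = _count_gained(truth, sites, enhancer_rbps)
    truth["translation_boost_log2"] = np.where(
        truth["class"] == "lengthened",
        cfg.enhancer_boost_log2 * truth["enhancer_sites_gained"], 0.0)

    samples = [f"case_{i + 1:02d}" for i in range(cfg.n_case)] + \
              [f"ctrl_{i + 1:02d}" for i in range(cfg.n_control)]
    design = GroupDesign(pd.Series(["case"] * cfg.n_case + ["control"] * cfg.n_control,
                                   index=samples))

    # latent per-sample distal usage drives both coverage and isoform quant
    usage = np.empty((n, len(samples)))
    for i in range(n):
        usage[i, :cfg.n_case] = _sample_usage(pdui_case[i], cfg.pdui_concentration,
                                              cfg.n_case, rng)
        usage[i, cfg.n_case:] = _sample_usage(pdui_control[i], cfg.pdui_concentration,
                                              cfg.n_control, rng)
    if cfg.noise_model == "none":
        usage[:, :cfg.n_case] = pdui_case[:, None]
        usage[:, cfg.n_case:] = pdui_control[:, None]
    sample_pdui = pd.DataFrame(usage, index=pd.Index(gene_ids, name="gene_id"),
                               columns=samples)

    annotation: dict[str, UTRAnnotation] = {}
    coverage: dict[str, dict[str, np.ndarray]] = {}
    pos_cursor = 1000
    for i, gid in enumerate(gene_ids):
        strand = "+" if i % 2 == 0 else "-"
        annotation[gid] = UTRAnnotation(gid, "chrS", pos_cursor,
                                        pos_cursor + int(utr_length[i]), strand)
        pos_cursor += int(utr_length[i]) + 500
        coverage[gid] = {
            s: simulate_utr_coverage(int(utr_length[i]), int(proximal_pos[i]),
                                     float(usage[i, j]), cfg.mean_depth, rng,
                                     noise_model=cfg.noise_model,
                                     dispersion=cfg.depth_dispersion)
            for j, s in enumerate(samples)
        }

    mrna, protein = simulate_expression(truth, cfg, design, rng)
    quant = _simulate_isoform_quant(truth, sample_pdui, mrna, cfg, rng)

    truth = truth.set_index("gene_id", drop=False)
    return SyntheticCohort(cfg, annotation, coverage, quant, mrna, protein,
                           sites, rbp_truth, truth, sample_pdui, design)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, str]:
    """Write every cohort component as plain text; returns the file manifest.

    All writers stamp a header comment with the tool version and config hash
    (no timestamps), so identical configs give byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"apalink v{__version__} config={cohort.config.config_hash()}"
    manifest: dict[str, str] = {}

    manifest["annotation"] = str(write_utr_annotation(
        cohort.annotation, out / "annotation.bed", header=tag))
    cov_dir = out / "coverage"
    cov_dir.mkdir(exist_ok=True)
    for s in cohort.design.samples:
        per_sample = {g: cohort.coverage[g][s] for g in cohort.coverage}
        manifest[f"coverage:{s}"] = str(write_bedgraph_coverage(
            per_sample, cohort.annotation, cov_dir / f"{s}.bedgraph", header=tag))
    manifest["isoform_quant"] = str(write_table(
        cohort.isoform_quant, out / "isoform_quant.tsv", header=tag))
    manifest["mrna"] = str(cohort.mrna.to_tsv(out / "mrna_fpkm.tsv", header=tag))
    manifest["protein"] = str(cohort.protein.to_tsv(out / "protein_ibaq.tsv", header=tag))
    manifest["rbp_sites"] = str(cohort.rbp_sites.to_bed6(out / "rbp_sites.bed", header=tag))
    manifest["design"] = str(cohort.design.to_tsv(out / "design.tsv", header=tag))
    manifest["truth"] = str(write_table(
        cohort.truth.reset_index(drop=True), out / "truth.tsv", header=tag))
    manifest["rbp_truth"] = str(write_table(cohort.rbp_truth, out / "rbp_truth.tsv", header=tag))
    manifest["sample_pdui"] = str(write_table(
        cohort.sample_pdui.reset_index(), out / "sample_pdui.tsv", header=tag))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest"] = str(out / "manifest.json")
    return manifest
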