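"""RNA-binding-protein site gain in extended 3'UTRs and the translation
enhancement screen.

When a gene's 3'UTR lengthens, the segment between the proximal poly(A) site
(the fitted breakpoint) and the distal UTR end — the *extended region* — is
present only in the long isoform, so any binding site overlapping it is
*gained* upon lengthening.  The screen asks, per RBP, whether genes bound by
it (>= 1 site anywhere in the 3'UTR) show a higher protein-per-mRNA FC ratio
than unbound genes: the effect size is the difference of group medians of
log2 FC ratio and significance is a two-sided Wilcoxon rank-sum; an RBP is
flagged a translation enhancer when the median difference is positive and
raw p < 0.05 (a BH q-value is reported alongside).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import bh_fdr, rank_sum_test
from .io import RBPSiteSet


def extended_region(breakpoint: int, utr_length: int) -> tuple[int, int]:
    """The (proximal, distal] segment gained by lengthening, as a 0-based
    half-open interval [breakpoint, utr_length)."""
    if not 0 < breakpoint < utr_length:
        raise ValueError(f"breakpoint {breakpoint} outside (0, {utr_length})")
    return int(breakpoint), int(utr_length)


def count_gained_sites(region: tuple[int, int], sites: RBPSiteSet, gene_id: str,
                       min_overlap: int = 1) -> dict[str, int]:
    """Per-RBP count of this gene's sites overlapping the extended region by
    at least ``min_overlap`` bp (any-overlap rule by default)."""
    lo, hi = region
    sub = sites.sites[sites.sites["gene_id"] == gene_id]
    if sub.empty:
        return {}
    ov = np.minimum(sub["end"], hi) - np.maximum(sub["start"], lo)
    gained = sub[ov >= min_overlap]
    return gained.groupby("rbp").size().to_dict()


def gains_table(apa_table: pd.DataFrame, annotation, sites: RBPSiteSet,
                min_overlap: int = 1) -> pd.DataFrame:
    """Long table (gene_id, rbp, n_gained_sites) over all lengthened genes."""
    rows = []
    lengthened = apa_table[apa_table["class"] == "lengthened"]
    for gene, row in lengthened.iterrows():
        bp = row.get("breakpoint")
        ann = annotation.get(gene)
        if ann is None or bp is None or not np.isfinite(bp):
            continue
        region = extended_region(int(bp), ann.utr_length)
        for rbp, n in sorted(count_gained_sites(region, sites, gene, min_overlap).items()):
            rows.append({"gene_id": gene, "rbp": rbp, "n_gained_sites": int(n)})
    return pd.DataFrame(rows, columns=["gene_id", "rbp", "n_gained_sites"])


def fraction_with_gain(lengthened_genes, gains: pd.DataFrame) -> dict:
    """Fraction of lengthened genes gaining >= 1 site of any RBP."""
    genes = list(lengthened_genes)
    with_gain = set(gains.loc[gains["n_gained_sites"] > 0, "gene_id"]) & set(genes)
    n = len(genes)
    return {"n_lengthened": n, "n_with_gain": len(with_gain),
            "fraction": len(with_gain) / n if n else 0.0}


def rbp_translation_enhancement_test(fc_ratio: pd.DataFrame, sites: RBPSiteSet,
                                     min_bound: int = 5, p_cut: float = 0.05) -> pd.DataFrame:
    """Per-RBP bound-vs-unbound screen on log2 protein-per-mRNA FC ratio.

    ``fc_ratio`` is the matched-gene table with a ``fc_ratio`` column (linear
    scale).  Bound = the gene has >= 1 site for the RBP anywhere in its
    3'UTR.  RBPs with fewer than ``min_bound`` bound matched genes, or with
    no unbound genes, are not testable.
    """
    log2_ratio = np.log2(fc_ratio["fc_ratio"].astype(float))
    genes = set(fc_ratio.index)
    rows = []
    for rbp in sites.rbp_names:
        bound = sites.bound_genes(rbp) & genes
        unbound = genes - bound
        if len(bound) < min_bound or not unbound:
            rows.append({"rbp": rbp, "n_bound": len(bound), "n_unbound": len(unbound),
                         "log2_delta_fc_ratio": np.nan, "p_value": np.nan,
                         "testable": False})
            continue
        b = log2_ratio.loc[sorted(bound)].to_numpy()
        u = log2_ratio.loc[sorted(unbound)].to_numpy()
        delta = float(np.median(b) - np.median(u))
        rows.append({"rbp": rbp, "n_bound": len(bound), "n_unbound": len(unbound),
                     "log2_delta_fc_ratio": delta, "p_value": rank_sum_test(b, u),
                     "testable": True})
    out = pd.DataFrame(rows).set_index("rbp")
    out["q_value"] = bh_fdr(out["p_value"])
    out["enhancer_flag"] = (out["log2_delta_fc_ratio"] > 0) & (out["p_value"] < p_cut)
    return out


class RBPGainAnalysis:
    """Model combining APA calls, binding sites and FC ratios.

    ``fit()`` returns :class:`RBPGainResults` with the per-gene gain table,
    the fraction of lengthened genes gaining any site, and the per-RBP
    translation-enhancement screen.
    """

    def __init__(self, apa_table: pd.DataFrame, annotation, sites: RBPSiteSet,
                 fc_ratio: pd.DataFrame, *, min_overlap: int = 1,
                 min_bound: int = 5, p_cut: float = 0.05):
        self.apa_table = apa_table
        self.annotation = annotation
        self.sites = sites
        self.fc_ratio = fc_ratio
        self.params = dict(min_overlap=min_overlap, min_bound=min_bound, p_cut=p_cut)

    def fit(self) -> "RBPGainResults":
        gains = gains_table(self.apa_table, self.annotation, self.sites,
                            min_overlap=self.params["min_overlap"])
        lengthened = self.apa_table.index[self.apa_table["class"] == "lengthened"]
        gain_frac = fraction_with_gain(lengthened, gains)
        enrichment = rbp_translation_enhancement_test(
            self.fc_ratio, self.sites, min_bound=self.params["min_bound"],
            p_cut=self.params["p_cut"])
        return RBPGainResults(gains, gain_frac, enrichment, self.params)


class RBPGainResults:
    def __init__(self, gains: pd.DataFrame, gain_fraction: dict,
                 enrichment: pd.DataFrame, params: dict):
        self.gains = gains
        self.gain_fraction = gain_fraction
        self.enrichment = enrichment
        self.params = dict(params)

    @property
    def enhancer_rbps(self) -> list[str]:
        return list(self.enrichment.index[self.enrichment["enhancer_flag"]])

    def summary(self) -> str:
        gf = self.gain_fraction
        return "\n".join([
            "RBP site gain in extended 3'UTRs",
            f"  lengthened genes           : {gf['n_lengthened']}",
            f"  with >=1 gained site       : {gf['n_with_gain']} "
            f"({gf['fraction']:.1%})" if gf["n_lengthened"] else
            "  with >=1 gained site       : 0",
            f"  RBPs screened              : {int(self.enrichment['testable'].sum())}"
            f" of {len(self.enrichment)}",
            f"  translation-enhancer RBPs  : {len(self.enhancer_rbps)}",
        ])
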