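"""Annotation-based distal poly(A)-site usage (DPAU) from isoform abundances.

DPAU for a gene in a sample is the percentage of total 3'UTR isoform
expression carried by the distal isoform(s) — those whose poly(A) site sits
at the maximal offset from the stop codon.  Isoforms at intermediate sites
count only in the denominator.  Event calling mirrors the coverage-based
stage on the 0–100 scale: lengthened when delta DPAU > 10 and p <= 0.05,
shortened when delta DPAU < -10 and p <= 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dapars import APAResults, call_apa_events
from .io import GroupDesign


def compute_dpau(gene_quant: pd.DataFrame, sample: str, min_total: float = 0.0) -> float:
    """DPAU (percent) for one gene in one sample.

    ``gene_quant`` holds that gene's isoform rows with columns ``pas_offset``
    and per-sample abundances.  Zero (or sub-floor) total expression gives
    NaN; a single-isoform gene is not quantifiable.
    """
    if gene_quant["pas_offset"].nunique() < 2:
        raise ValueError("gene has fewer than two distinct poly(A) sites")
    ab = gene_quant[sample].to_numpy(dtype=float)
    total = np.nansum(ab)
    if total <= 0 or total < min_total:
        return float("nan")
    distal = gene_quant["pas_offset"] == gene_quant["pas_offset"].max()
    return 100.0 * float(np.nansum(ab[distal.to_numpy()])) / float(total)


def compute_dpau_table(quant: pd.DataFrame, samples: list[str],
                       min_total: float = 1.0) -> pd.DataFrame:
    """Genes x samples DPAU table; single-PAS genes are dropped as untestable."""
    rows = {}
    for gene, sub in quant.groupby("gene_id", sort=True):
        if sub["pas_offset"].nunique() < 2:
            continue
        distal = (sub["pas_offset"] == sub["pas_offset"].max()).to_numpy()
        vals = sub[samples].to_numpy(dtype=float)
        total = np.nansum(vals, axis=0)
        dist_sum = np.nansum(vals[distal], axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dpau = np.where((total > 0) & (total >= min_total),
                            100.0 * dist_sum / total, np.nan)
        rows[gene] = dpau
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples) \
        .rename_axis("gene_id")


def call_dpau_events(dpau: pd.DataFrame, design: GroupDesign, delta_cut: float = 10.0,
                     p_cut: float = 0.05, min_per_group: int = 3,
                     bh_adjust: bool = False) -> pd.DataFrame:
    """Event calling on the DPAU (0-100) scale; same decision as the PDUI stage."""
    return call_apa_events(dpau, design, delta_cut=delta_cut, p_cut=p_cut,
                           min_per_group=min_per_group, bh_adjust=bh_adjust)


def concordance(dapars_table: pd.DataFrame, qapa_table: pd.DataFrame) -> dict:
    """Cross-tabulate two callers' event classes on their shared gene set.

    Returns the class x class crosstab plus the fraction of first-caller
    lengthened genes also called lengthened by the second.
    """
    shared = dapars_table.index.intersection(qapa_table.index)
    a = dapars_table.loc[shared, "class"]
    b = qapa_table.loc[shared, "class"]
    tab = pd.crosstab(a, b, rownames=["dapars"], colnames=["qapa"])
    lengthened = a.index[a == "lengthened"]
    frac = float((b.loc[lengthened] == "lengthened").mean()) if len(lengthened) else float("nan")
    return {"crosstab": tab, "n_shared": int(len(shared)),
            "fraction_lengthened_concordant": frac}


class IsoformAPA:
    """Annotation-based APA model over an isoform abundance table.

    ``quant`` columns: gene_id, isoform_id, pas_offset, one column per
    sample.  ``min_total`` is the expression floor below which a gene is not
    quantifiable in a sample.
    """

    def __init__(self, quant: pd.DataFrame, design: GroupDesign, *,
                 delta_cut: float = 10.0, p_cut: float = 0.05,
                 min_total: float = 1.0, min_per_group: int = 3,
                 bh_adjust: bool = False):
        self.quant = quant
        self.design = design
        self.params = dict(delta_cut=delta_cut, p_cut=p_cut, min_total=min_total,
                           min_per_group=min_per_group, bh_adjust=bh_adjust)

    def fit(self) -> APAResults:
        dpau = compute_dpau_table(self.quant, self.design.samples,
                                  min_total=self.params["min_total"])
        table = call_dpau_events(dpau, self.design,
                                 delta_cut=self.params["delta_cut"],
                                 p_cut=self.params["p_cut"],
                                 min_per_group=self.params["min_per_group"],
                                 bh_adjust=self.params["bh_adjust"])
        return APAResults(dpau, table, "DPAU", self.design, self.params)
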