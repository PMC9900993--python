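"""Proteogenomic integration: protein-per-mRNA fold-change ratios, APA x
expression cross-tabulation and usage-protein correlation.

The protein-per-mRNA FC ratio of a gene is its protein fold change (case /
control) divided by its mRNA fold change, on linear scale; ratios above 1
indicate regulation at the translation level.  Matched genes (quantified at
both layers) are partitioned into ``de_any`` (differentially expressed at
either layer) and ``unchanged`` (at neither); the differential set typically
splits into a positive-ratio and a negative-ratio subpopulation on the log10
scale.
"""

from __future__ import annotations

import json
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import rank_sum_test
from .io import GroupDesign


def match_pairs(mrna_de: pd.DataFrame, protein_de: pd.DataFrame) -> pd.DataFrame:
    """Intersect the two DE tables by gene and partition by DE status.

    Returns one row per matched gene carrying both layers' fold changes and
    statuses plus ``de_set`` in {de_any, unchanged}.
    """
    shared = mrna_de.index.intersection(protein_de.index)
    out = mrna_de.loc[shared].add_suffix("_mrna").join(
        protein_de.loc[shared].add_suffix("_protein"))
    de = (out["status_mrna"].isin(["up", "down"])
          | out["status_protein"].isin(["up", "down"]))
    out["de_set"] = np.where(de, "de_any", "unchanged")
    return out


def compute_fc_ratio(matched: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-gene protein-per-mRNA FC ratios plus per-set medians.

    Ratios are taken on linear case/control scale so the log10 transform is
    well defined.  For the ``de_any`` set the positive- and negative-sign
    log10 subpopulations are summarised separately (the differential set is
    characteristically bimodal).
    """
    fc_m = matched["fc_linear_mrna"].to_numpy(dtype=float)
    fc_p = matched["fc_linear_protein"].to_numpy(dtype=float)
    if np.any(fc_m <= 0) or np.any(fc_p <= 0) or np.any(~np.isfinite(fc_m) | ~np.isfinite(fc_p)):
        raise ValueError("fold changes must be positive and finite for FC-ratio analysis")
    table = pd.DataFrame({
        "fc_mrna_linear": fc_m,
        "fc_protein_linear": fc_p,
        "fc_ratio": fc_p / fc_m,
        "log10_fc_ratio": np.log10(fc_p) - np.log10(fc_m),
        "de_set": matched["de_set"].to_numpy(),
    }, index=matched.index)
    de = table[table["de_set"] == "de_any"]["log10_fc_ratio"]
    pos, neg = de[de > 0], de[de < 0]
    summary = {
        "n_matched": int(len(table)),
        "n_unchanged": int((table["de_set"] == "unchanged").sum()),
        "n_de_any": int(len(de)),
        "median_log10_fc_ratio_all": float(table["log10_fc_ratio"].median()),
        "median_log10_fc_ratio_unchanged":
            float(table.loc[table["de_set"] == "unchanged", "log10_fc_ratio"].median()),
        "median_log10_fc_ratio_de_positive": float(pos.median()) if len(pos) else float("nan"),
        "median_log10_fc_ratio_de_negative": float(neg.median()) if len(neg) else float("nan"),
        "prop_de_positive": float(len(pos) / len(de)) if len(de) else float("nan"),
        "prop_de_negative": float(len(neg) / len(de)) if len(de) else float("nan"),
    }
    return table, summary


def fc_ratio_group_test(de_records: Iterable[float], unchanged_records: Iterable[float]) -> dict:
    """Two-sided Mann-Whitney U comparing log10 FC ratios of the differential
    and unchanged gene sets."""
    x = np.asarray(list(de_records), dtype=float)
    y = np.asarray(list(unchanged_records), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both gene sets must be non-empty")
    return {"p_value": rank_sum_test(x, y),
            "median_de": float(np.median(x)), "median_unchanged": float(np.median(y))}


def crosstab_apa_expression(apa_table: pd.DataFrame, mrna_de: pd.DataFrame,
                            protein_de: pd.DataFrame) -> pd.DataFrame:
    """Per APA class and omics layer: how many matched genes are up / down.

    Rows are (APA class, layer); genes are restricted to the mRNA-protein
    matched set.  Fractions are NaN for empty classes.
    """
    matched = mrna_de.index.intersection(protein_de.index)
    rows = []
    for cls, sub in apa_table.groupby("class"):
        genes = sub.index.intersection(matched)
        for layer, de in (("mrna", mrna_de), ("protein", protein_de)):
            status = de.loc[genes, "status"]
            n, n_up, n_down = len(genes), int((status == "up").sum()), int((status == "down").sum())
            rows.append({
                "apa_class": cls, "layer": layer, "n_total": n,
                "n_up": n_up, "n_down": n_down,
                "fraction_up": n_up / n if n else float("nan"),
                "fraction_down": n_down / n if n else float("nan"),
            })
    return pd.DataFrame(rows)


def correlate_usage_protein(usage: pd.DataFrame, protein: pd.DataFrame,
                            metric: str = "PDUI", min_pairs: int = 6,
                            p_cut: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Per-gene Spearman correlation of poly(A)-site usage with protein
    abundance across samples.

    Genes need at least ``min_pairs`` samples quantified in both tables;
    constant vectors give NaN.  The summary counts significant positive and
    negative correlations and their median coefficients.
    """
    shared_genes = usage.index.intersection(protein.index)
    shared_samples = [s for s in usage.columns if s in protein.columns]
    rows = []
    for gene in shared_genes:
        u = usage.loc[gene, shared_samples].to_numpy(dtype=float)
        p = protein.loc[gene, shared_samples].to_numpy(dtype=float)
        ok = ~np.isnan(u) & ~np.isnan(p)
        if ok.sum() < min_pairs:
            continue
        u, p = u[ok], p[ok]
        if np.all(u == u[0]) or np.all(p == p[0]):
            rows.append({"gene_id": gene, "spearman_r": np.nan, "p_value": np.nan,
                         "n": int(ok.sum()), "usage_metric": metric})
            continue
        r, pv = stats.spearmanr(u, p)
        rows.append({"gene_id": gene, "spearman_r": float(r), "p_value": float(pv),
                     "n": int(ok.sum()), "usage_metric": metric})
    table = pd.DataFrame(rows, columns=["gene_id", "spearman_r", "p_value", "n",
                                        "usage_metric"]).set_index("gene_id")
    sig = table.dropna(subset=["p_value"])
    sig = sig[sig["p_value"] < p_cut]
    pos, neg = sig[sig["spearman_r"] > 0], sig[sig["spearman_r"] < 0]
    summary = {
        "n_tested": int(len(table)), "n_significant": int(len(sig)),
        "n_positive": int(len(pos)), "n_negative": int(len(neg)),
        "median_r_positive": float(pos["spearman_r"].median()) if len(pos) else float("nan"),
        "median_r_negative": float(neg["spearman_r"].median()) if len(neg) else float("nan"),
    }
    return table, summary


class IntegrationResults:
    """Matched-pair FC-ratio analysis plus APA cross-tabulation."""

    def __init__(self, matched: pd.DataFrame, fc_ratio: pd.DataFrame,
                 fc_summary: dict, group_test: dict,
                 crosstab: pd.DataFrame | None, correlation: pd.DataFrame | None,
                 correlation_summary: dict | None):
        self.matched = matched
        self.fc_ratio = fc_ratio
        self.fc_summary = fc_summary
        self.group_test = group_test
        self.crosstab = crosstab
        self.correlation = correlation
        self.correlation_summary = correlation_summary

    def summary(self) -> str:
        s = self.fc_summary
        lines = [
            "mRNA-protein integration",
            f"  matched pairs            : {s['n_matched']}",
            f"  differential (either)    : {s['n_de_any']}",
            f"  unchanged (neither)      : {s['n_unchanged']}",
            f"  median log10 FC ratio    : all {s['median_log10_fc_ratio_all']:+.3f}, "
            f"unchanged {s['median_log10_fc_ratio_unchanged']:+.3f}",
            f"  differential subpop medians: +{s['median_log10_fc_ratio_de_positive']:.3f} "
            f"({s['prop_de_positive']:.0%}) / {s['median_log10_fc_ratio_de_negative']:.3f} "
            f"({s['prop_de_negative']:.0%})",
            f"  Mann-Whitney de vs unchanged p = {self.group_test['p_value']:.3g}",
        ]
        return "\n".join(lines)

    def to_json(self, path):
        payload = {"fc_ratio": self.fc_summary, "group_test": self.group_test}
        if self.correlation_summary is not None:
            payload["usage_protein_correlation"] = self.correlation_summary
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return path

    def plot_fc_ratio(self, ax=None, bins: int = 60):
        """Histogram of log10 FC ratio for unchanged vs differential genes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, color in (("unchanged", "0.6"), ("de_any", "crimson")):
            vals = self.fc_ratio.loc[self.fc_ratio["de_set"] == name, "log10_fc_ratio"]
            ax.hist(vals, bins=bins, alpha=0.6, label=name, color=color)
        ax.set_xlabel("log10 protein-per-mRNA FC ratio")
        ax.set_ylabel("genes")
        ax.legend()
        return ax


class ProteogenomicsIntegration:
    """Model tying APA calls to the two DE layers.

    Parameters are results objects from the upstream stages; ``protein_ifot``
    and ``usage`` enable the optional per-gene usage-protein correlation.
    """

    def __init__(self, mrna_de: pd.DataFrame, protein_de: pd.DataFrame,
                 apa_table: pd.DataFrame | None = None, *,
                 usage: pd.DataFrame | None = None,
                 protein_values: pd.DataFrame | None = None,
                 usage_metric: str = "PDUI", min_pairs: int = 6):
        self.mrna_de = mrna_de
        self.protein_de = protein_de
        self.apa_table = apa_table
        self.usage = usage
        self.protein_values = protein_values
        self.usage_metric = usage_metric
        self.min_pairs = min_pairs

    def fit(self) -> IntegrationResults:
        matched = match_pairs(self.mrna_de, self.protein_de)
        usable = matched[(matched["fc_linear_mrna"] > 0) & (matched["fc_linear_protein"] > 0)
                         & np.isfinite(matched["fc_linear_mrna"])
                         & np.isfinite(matched["fc_linear_protein"])]
        fc_ratio, fc_summary = compute_fc_ratio(usable)
        de_vals = fc_ratio.loc[fc_ratio["de_set"] == "de_any", "log10_fc_ratio"]
        un_vals = fc_ratio.loc[fc_ratio["de_set"] == "unchanged", "log10_fc_ratio"]
        if len(de_vals) and len(un_vals):
            gt = fc_ratio_group_test(de_vals, un_vals)
        else:  # a degenerate partition (e.g. a null cohort with no DE genes)
            gt = {"p_value": float("nan"),
                  "median_de": float(np.median(de_vals)) if len(de_vals) else float("nan"),
                  "median_unchanged": float(np.median(un_vals)) if len(un_vals) else float("nan")}
        crosstab = None
        if self.apa_table is not None:
            crosstab = crosstab_apa_expression(self.apa_table, self.mrna_de, self.protein_de)
        corr = corr_summary = None
        if self.usage is not None and self.protein_values is not None:
            corr, corr_summary = correlate_usage_protein(
                self.usage, self.protein_values, metric=self.usage_metric,
                min_pairs=self.min_pairs)
        return IntegrationResults(matched, fc_ratio, fc_summary, gt, crosstab,
                                  corr, corr_summary)
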