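"""Expression preprocessing and rank-based differential expression.

Both omics layers go through the same nonparametric machinery: per-gene
two-sided Wilcoxon rank-sum between case and control with Benjamini-Hochberg
FDR across tested genes.  Fold changes are ratios of group medians (robust,
consistent with rank testing); genes pass as differentially expressed when
the linear fold change is >= 2 (or <= 1/2) and FDR <= 0.01.

Proteomics-specific preprocessing follows the iBAQ workflow: per-sample
fraction-of-total (FOT) normalisation, scaled by 1e5 to iFOT, and a
detection filter keeping proteins observed in at least one-tenth of samples.
mRNA preprocessing keeps transcripts whose maximal FPKM reaches 1.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr, rank_sum_test
from .io import AbundanceMatrix, GroupDesign, write_table

log = logging.getLogger(__name__)

DE_STATUSES = ("up", "down", "unchanged", "not_testable")


def filter_expressed_transcripts(m: AbundanceMatrix, min_max_fpkm: float = 1.0) -> AbundanceMatrix:
    """Keep transcripts effectively expressed: max FPKM across samples >= floor."""
    if m.unit != "FPKM":
        raise ValueError(f"expected an FPKM matrix, got unit {m.unit!r}")
    keep = m.values.max(axis=1, skipna=True) >= min_max_fpkm
    return AbundanceMatrix(m.values.loc[keep], unit=m.unit)


def normalize_ifot(m: AbundanceMatrix, scale: float = 1e5) -> AbundanceMatrix:
    """iBAQ -> FOT -> iFOT: per-sample fraction of total, scaled by 1e5.

    Missing entries stay missing and do not contribute to the per-sample sum.
    """
    if m.unit != "iBAQ":
        raise ValueError(f"expected an iBAQ matrix, got unit {m.unit!r}")
    sums = m.values.sum(axis=0, skipna=True)
    dead = sums.index[(sums <= 0) | m.values.isna().all(axis=0)]
    if len(dead):
        raise ValueError(f"sample(s) with no detected protein: {list(dead)[:5]}")
    return AbundanceMatrix(m.values.div(sums, axis=1) * scale, unit="iFOT")


def filter_detected_proteins(m: AbundanceMatrix, min_fraction: float = 0.1) -> AbundanceMatrix:
    """Keep proteins detected in at least ``ceil(min_fraction * n_samples)``
    samples ("at least one-tenth" rounds up)."""
    need = math.ceil(min_fraction * len(m.samples))
    keep = m.values.notna().sum(axis=1) >= need
    return AbundanceMatrix(m.values.loc[keep], unit=m.unit)


def _fold_changes(case_median: np.ndarray, ctrl_median: np.ndarray,
                  epsilon: float) -> tuple[np.ndarray, np.ndarray]:
    """Linear and signed fold changes from group medians.

    ``epsilon`` (half the smallest positive value in the matrix) is added to
    both medians only when one of them is zero, keeping the ratio defined.
    """
    zero = (case_median == 0) | (ctrl_median == 0)
    num = np.where(zero, case_median + epsilon, case_median)
    den = np.where(zero, ctrl_median + epsilon, ctrl_median)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = num / den
        signed = np.where(fc >= 1, fc, -1.0 / fc)
    return fc, signed


def differential_test(m: AbundanceMatrix, design: GroupDesign, fc_cut: float = 2.0,
                      fdr_cut: float = 0.01, min_per_group: int = 3) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE table with BH FDR and median fold changes.

    Returns a DataFrame indexed by gene_id with columns n_case, n_control,
    median_case, median_control, fc_linear, fc_signed, p_value, fdr, status.
    """
    missing = set(design.samples) - set(m.samples)
    if missing:
        raise ValueError(f"design samples absent from matrix: {sorted(missing)[:5]}")
    case = m.values[design.case_samples].to_numpy(dtype=float)
    ctrl = m.values[design.control_samples].to_numpy(dtype=float)
    n_case = (~np.isnan(case)).sum(axis=1)
    n_ctrl = (~np.isnan(ctrl)).sum(axis=1)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med_case = np.nanmedian(case, axis=1)
        med_ctrl = np.nanmedian(ctrl, axis=1)
    arr = m.values.to_numpy(dtype=float)
    positive = arr[np.isfinite(arr) & (arr > 0)]
    epsilon = 0.5 * positive.min() if positive.size else 0.5
    fc, signed = _fold_changes(med_case, med_ctrl, epsilon)
    testable = (n_case >= min_per_group) & (n_ctrl >= min_per_group)
    pvals = np.full(len(arr), np.nan)
    for i in np.flatnonzero(testable):
        pvals[i] = rank_sum_test(case[i], ctrl[i])
    fdr = bh_fdr(pvals)
    status = np.where(~testable, "not_testable",
                      np.where((fc >= fc_cut) & (fdr <= fdr_cut), "up",
                               np.where((fc <= 1.0 / fc_cut) & (fdr <= fdr_cut), "down",
                                        "unchanged")))
    return pd.DataFrame({
        "n_case": n_case, "n_control": n_ctrl,
        "median_case": med_case, "median_control": med_ctrl,
        "fc_linear": fc, "fc_signed": signed,
        "p_value": pvals, "fdr": fdr, "status": status,
    }, index=m.values.index.rename("gene_id"))


def normality_check(m: AbundanceMatrix, design: GroupDesign) -> pd.DataFrame:
    """Advisory per-gene, per-group Shapiro-Wilk p-values.

    The pipeline always uses rank tests; this table only documents how far
    each gene departs from normality.  Constant vectors or n < 3 give NaN.
    """
    out = {}
    for name, samples in (("case", design.case_samples), ("control", design.control_samples)):
        ps = []
        for _, row in m.values[samples].iterrows():
            x = row.dropna().to_numpy(dtype=float)
            if x.size < 3 or np.all(x == x[0]):
                ps.append(np.nan)
            else:
                ps.append(float(stats.shapiro(x).pvalue))
        out[f"shapiro_p_{name}"] = ps
    return pd.DataFrame(out, index=m.values.index.rename("gene_id"))


def pca_embed(m: AbundanceMatrix, k: int = 2, log_transform: bool = True,
              pseudocount: float = 1.0) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates on the first ``k`` principal axes.

    The matrix is log2(x + pseudocount) transformed and gene-centred; genes
    with any missing value are dropped.  Sign convention: the gene loading of
    largest magnitude on each axis is positive.  Returns (coordinates,
    explained variance ratio); fewer axes with a warning if rank < k.
    """
    if len(m.samples) < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    vals = m.values.dropna(axis=0, how="any")
    if len(vals) < len(m.values):
        log.warning("pca: dropped %d genes with missing values", len(m.values) - len(vals))
    X = np.log2(vals.to_numpy(dtype=float) + pseudocount) if log_transform \
        else vals.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)  # centre each gene across samples
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((S > S.max() * max(X.shape) * np.finfo(float).eps).sum()) if S.size else 0
    k_eff = min(k, rank)
    if k_eff < k:
        log.warning("pca: matrix rank %d < requested %d axes", rank, k)
    coords = np.empty((len(m.samples), k_eff))
    for j in range(k_eff):
        flip = -1.0 if U[np.argmax(np.abs(U[:, j])), j] < 0 else 1.0
        coords[:, j] = flip * S[j] * Vt[j, :]
    explained = (S[:k_eff] ** 2) / (S**2).sum() if S.size else np.array([])
    return (pd.DataFrame(coords, index=pd.Index(m.samples, name="sample_id"),
                         columns=[f"PC{j + 1}" for j in range(k_eff)]),
            explained)


class DEResults:
    """Differential-expression results for one omics layer."""

    def __init__(self, table: pd.DataFrame, design: GroupDesign, unit: str, params: dict):
        self.table = table
        self.design = design
        self.unit = unit
        self.params = dict(params)

    @property
    def counts(self) -> dict[str, int]:
        c = self.table["status"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in DE_STATUSES}

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["status"].isin(["up", "down"])])

    def summary(self) -> str:
        c = self.counts
        return "\n".join([
            f"Differential expression ({self.unit}; FC cut {self.params.get('fc_cut')}, "
            f"FDR cut {self.params.get('fdr_cut')})",
            f"  genes tested : {int((self.table['status'] != 'not_testable').sum())}",
            f"  up in case   : {c['up']}",
            f"  down in case : {c['down']}",
            f"  unchanged    : {c['unchanged']}",
            f"  not testable : {c['not_testable']}",
        ])

    def to_tsv(self, path, header: str | None = None):
        return write_table(self.table.reset_index(), path, header=header)

    def plot_volcano(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table.dropna(subset=["p_value"])
        with np.errstate(divide="ignore"):
            x = np.sign(t["fc_signed"]) * np.log2(np.abs(t["fc_signed"]))
        y = -np.log10(np.maximum(t["fdr"], 1e-300))
        colors = t["status"].map({"up": "crimson", "down": "steelblue"}).fillna("0.7")
        ax.scatter(x, y, s=6, c=colors, linewidths=0)
        ax.set_xlabel("signed log2 fold change (case / control)")
        ax.set_ylabel("-log10 FDR")
        return ax


class WilcoxonDE:
    """Rank-based differential-expression model for an abundance matrix."""

    def __init__(self, m: AbundanceMatrix, design: GroupDesign, *, fc_cut: float = 2.0,
                 fdr_cut: float = 0.01, min_per_group: int = 3):
        self.m = m
        self.design = design
        self.params = dict(fc_cut=fc_cut, fdr_cut=fdr_cut, min_per_group=min_per_group)

    def fit(self) -> DEResults:
        table = differential_test(self.m, self.design, **self.params)
        return DEResults(table, self.design, self.m.unit, self.params)
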