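"""De novo two-isoform change-point estimation of distal poly(A)-site usage.

The model: a gene's 3'UTR carries two isoforms sharing a 5' end — a long
isoform spanning the full UTR at constant read depth ``alpha`` and a short
isoform ending at an unknown proximal poly(A) site (the breakpoint) adding
depth ``beta`` before it:

    depth(x) ~ alpha + beta * 1[x < breakpoint],   alpha, beta >= 0

PDUI (percentage of distal poly(A)-site usage index) is the long-isoform
share ``alpha / (alpha + beta)``.  The breakpoint is a property of the gene,
so it is estimated jointly over all samples by minimising the summed residual
sum of squares over a candidate grid; per-sample abundances are then the
segment means at that shared breakpoint.  Group comparison is the difference
of group median PDUI with a two-sided Wilcoxon rank-sum p-value; genes pass
as lengthened when delta > 0.1 and p <= 0.05, shortened when delta < -0.1 and
p <= 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from ._stats import bh_fdr, rank_sum_test
from .io import GroupDesign, UTRAnnotation, write_table

EVENT_CLASSES = ("lengthened", "shortened", "unchanged", "not_testable")


class SegmentFit(NamedTuple):
    alpha: float  # long-isoform depth (distal segment mean)
    beta: float   # short-isoform depth on top of alpha, proximal of breakpoint
    rss: float
    degenerate: bool  # True when the unconstrained beta was negative and clamped


@dataclass
class TwoIsoformFit:
    """Joint two-isoform fit for one gene across samples."""

    gene_id: str
    breakpoint: int | None
    long_abundance: dict[str, float] = field(default_factory=dict)
    short_abundance: dict[str, float] = field(default_factory=dict)
    rss: float = float("nan")
    qc_flag: str = "ok"  # ok | low_coverage | degenerate
    samples_used: list[str] = field(default_factory=list)


def fit_segment_means(depth: np.ndarray, breakpoint: int) -> SegmentFit:
    """Least-squares segment means for a fixed breakpoint.

    Unconstrained optimum: ``alpha = mean(depth[breakpoint:])`` and
    ``alpha + beta = mean(depth[:breakpoint])``.  A rising profile (distal
    mean above proximal mean) would give beta < 0; it is clamped to the
    boundary ``beta = 0, alpha = mean(depth)`` and flagged degenerate.
    """
    d = np.asarray(depth, dtype=float)
    b = int(breakpoint)
    if not 0 < b < d.size:
        raise ValueError(f"breakpoint {b} leaves an empty segment (length {d.size})")
    m_prox = d[:b].mean()
    m_dist = d[b:].mean()
    if m_prox >= m_dist:
        alpha, beta, degenerate = m_dist, m_prox - m_dist, False
    else:
        alpha, beta, degenerate = d.mean(), 0.0, True
    pred = np.where(np.arange(d.size) < b, alpha + beta, alpha)
    rss = float(((d - pred) ** 2).sum())
    return SegmentFit(float(alpha), float(beta), rss, degenerate)


def _rss_grid(depth: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """RSS of the clamped two-segment fit at each candidate breakpoint, O(n)."""
    d = np.asarray(depth, dtype=float)
    n = d.size
    s1 = np.concatenate([[0.0], np.cumsum(d)])
    s2 = np.concatenate([[0.0], np.cumsum(d * d)])
    b = np.asarray(candidates)
    n1 = b.astype(float)
    n2 = (n - b).astype(float)
    m1 = s1[b] / n1
    m2 = (s1[n] - s1[b]) / n2
    rss_free = s2[n] - n1 * m1**2 - n2 * m2**2
    grand = s1[n] / n
    rss_clamped = s2[n] - n * grand**2
    rss = np.where(m1 >= m2, rss_free, rss_clamped)
    return np.maximum(rss, 0.0)


def default_search(utr_length: int, margin_bp: int = 50, margin_frac: float = 0.05,
                   max_grid: int = 2000) -> np.ndarray:
    """Candidate breakpoint grid: a margin off each UTR end to avoid edge
    artifacts, stride 1 up to ``max_grid`` positions, coarser beyond."""
    margin = max(margin_bp, math.ceil(margin_frac * utr_length))
    lo, hi = margin, utr_length - margin
    if lo > hi:
        lo, hi = 1, utr_length - 1
    stride = max(1, math.ceil(utr_length / max_grid))
    return np.arange(lo, hi + 1, stride, dtype=int)


def proximal_depth(depth: np.ndarray, window: int = 100) -> float:
    """Mean depth over the 5'-most ``window`` bp of the 3'UTR.

    Both isoforms cover this shared region, so it measures total transcript
    abundance independently of distal usage; it is the quantity the coverage
    filter is applied to.
    """
    d = np.asarray(depth, dtype=float)
    return float(d[:min(window, d.size)].mean())


def fit_joint_breakpoint(profiles: Mapping[str, np.ndarray], gene_id: str = "",
                         search: np.ndarray | None = None,
                         min_coverage: float = 30.0,
                         coverage_window: int = 100) -> TwoIsoformFit:
    """Shared-breakpoint fit across samples of one gene.

    Samples whose proximal-window mean depth is below ``min_coverage`` are
    excluded; at least two must remain.  The breakpoint minimises the sum
    over samples of the per-sample clamped RSS; ties go to the smallest
    breakpoint.
    """
    lengths = {len(v) for v in profiles.values()}
    if len(lengths) != 1:
        raise ValueError(f"{gene_id}: coverage vectors differ in length")
    L = lengths.pop()
    used = [s for s, v in profiles.items()
            if proximal_depth(v, coverage_window) >= min_coverage]
    if len(used) < 2:
        return TwoIsoformFit(gene_id, None, qc_flag="low_coverage")
    candidates = default_search(L) if search is None else np.asarray(search, dtype=int)
    if candidates.size == 0:
        return TwoIsoformFit(gene_id, None, qc_flag="low_coverage")
    total = np.zeros(candidates.size)
    for s in used:
        total += _rss_grid(np.asarray(profiles[s], dtype=float), candidates)
    bp = int(candidates[int(np.argmin(total))])
    fit = TwoIsoformFit(gene_id, bp, rss=float(total.min()), samples_used=used)
    n_degenerate = 0
    for s in used:
        seg = fit_segment_means(profiles[s], bp)
        fit.long_abundance[s] = seg.alpha
        fit.short_abundance[s] = seg.beta
        n_degenerate += seg.degenerate
    if n_degenerate == len(used):
        fit.qc_flag = "degenerate"
    return fit


def compute_pdui(alpha: float, beta: float) -> float:
    """PDUI = long-isoform abundance over total; NaN when nothing is expressed."""
    if alpha < 0 or beta < 0:
        raise ValueError("abundances must be non-negative")
    total = alpha + beta
    return float("nan") if total == 0 else alpha / total


def call_apa_events(usage: pd.DataFrame, design: GroupDesign, delta_cut: float = 0.1,
                    p_cut: float = 0.05, min_per_group: int = 3,
                    bh_adjust: bool = False) -> pd.DataFrame:
    """Classify genes as lengthened / shortened / unchanged / not_testable.

    ``usage`` is a genes x samples table of PDUI (or DPAU) values, NaN where
    not quantifiable.  delta = median(case) - median(control); p from the
    two-sided Wilcoxon rank-sum on per-sample usage.  ``bh_adjust`` switches
    the significance column used for classing from raw p to BH q.
    """
    missing = set(design.samples) - set(usage.columns)
    if missing:
        raise ValueError(f"design samples absent from usage table: {sorted(missing)[:5]}")
    case = usage[design.case_samples].to_numpy(dtype=float)
    ctrl = usage[design.control_samples].to_numpy(dtype=float)
    n_case = (~np.isnan(case)).sum(axis=1)
    n_ctrl = (~np.isnan(ctrl)).sum(axis=1)
    import warnings
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med_case = np.nanmedian(case, axis=1)
        med_ctrl = np.nanmedian(ctrl, axis=1)
    delta = med_case - med_ctrl
    testable = (n_case >= min_per_group) & (n_ctrl >= min_per_group)
    pvals = np.full(len(usage), np.nan)
    for i in np.flatnonzero(testable):
        pvals[i] = rank_sum_test(case[i], ctrl[i])
    qvals = bh_fdr(pvals)
    sig = qvals if bh_adjust else pvals
    cls = np.where(~testable, "not_testable",
                   np.where((delta > delta_cut) & (sig <= p_cut), "lengthened",
                            np.where((delta < -delta_cut) & (sig <= p_cut), "shortened",
                                     "unchanged")))
    return pd.DataFrame({
        "n_case": n_case, "n_control": n_ctrl,
        "median_case": med_case, "median_control": med_ctrl,
        "delta": delta, "p_value": pvals, "q_value": qvals, "class": cls,
    }, index=usage.index.rename("gene_id"))


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class APAResults:
    """Per-gene usage estimates and group-level event calls.

    Attributes
    ----------
    usage : DataFrame
        genes x samples usage values (PDUI in [0,1] or DPAU in [0,100]).
    table : DataFrame
        per-gene medians, delta, p-value and event class (plus breakpoint and
        qc flag for coverage-based fits).
    metric : str
        "PDUI" or "DPAU".
    """

    def __init__(self, usage: pd.DataFrame, table: pd.DataFrame, metric: str,
                 design: GroupDesign, params: dict,
                 fits: dict[str, TwoIsoformFit] | None = None):
        self.usage = usage
        self.table = table
        self.metric = metric
        self.design = design
        self.params = dict(params)
        self.fits = fits or {}

    @property
    def counts(self) -> dict[str, int]:
        c = self.table["class"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in EVENT_CLASSES}

    def genes_in_class(self, cls: str) -> list[str]:
        return list(self.table.index[self.table["class"] == cls])

    @property
    def lengthened_genes(self) -> list[str]:
        return self.genes_in_class("lengthened")

    @property
    def shortened_genes(self) -> list[str]:
        return self.genes_in_class("shortened")

    def summary(self) -> str:
        c = self.counts
        n_event = c["lengthened"] + c["shortened"]
        lines = [
            f"{self.metric} event calls "
            f"(delta cut {self.params.get('delta_cut')}, p cut {self.params.get('p_cut')})",
            f"  genes analysed : {len(self.table)}",
            f"  lengthened     : {c['lengthened']}",
            f"  shortened      : {c['shortened']}",
            f"  unchanged      : {c['unchanged']}",
            f"  not testable   : {c['not_testable']}",
        ]
        if n_event:
            lines.append(f"  lengthened fraction of events: {c['lengthened'] / n_event:.3f}")
        return "\n".join(lines)

    def to_tsv(self, path, header: str | None = None):
        out = self.table.copy()
        usage = self.usage.add_prefix(f"{self.metric.lower()}_")
        out = out.join(usage)
        return write_table(out.reset_index(), path, header=header)

    def plot_volcano(self, ax=None):
        """Delta versus -log10 p, events highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table.dropna(subset=["p_value"])
        logp = -np.log10(np.maximum(t["p_value"], 1e-300))
        colors = t["class"].map({"lengthened": "crimson", "shortened": "steelblue"}).fillna("0.7")
        ax.scatter(t["delta"], logp, s=6, c=colors, linewidths=0)
        ax.axhline(-np.log10(self.params.get("p_cut", 0.05)), ls="--", lw=0.7, c="0.4")
        for cut in (self.params.get("delta_cut", 0.1), -self.params.get("delta_cut", 0.1)):
            ax.axvline(cut, ls="--", lw=0.7, c="0.4")
        ax.set_xlabel(f"delta {self.metric} (case - control)")
        ax.set_ylabel("-log10 p")
        return ax


class CoverageAPA:
    """De novo coverage-based APA model for a cohort.

    Parameters
    ----------
    coverage : mapping gene_id -> {sample_id -> depth vector}
        Transcript-oriented per-base 3'UTR read depth.
    annotation : mapping gene_id -> UTRAnnotation
    design : GroupDesign
    min_coverage : float
        Floor on the proximal-window mean depth for a sample to contribute to
        a gene.
    min_group_frac : float
        A gene is fitted only when at least this fraction of each group's
        samples passes the coverage floor.
    """

    def __init__(self, coverage: Mapping[str, Mapping[str, np.ndarray]],
                 annotation: Mapping[str, UTRAnnotation], design: GroupDesign, *,
                 delta_cut: float = 0.1, p_cut: float = 0.05,
                 min_coverage: float = 30.0, coverage_window: int = 100,
                 min_group_frac: float = 0.5,
                 min_per_group: int = 3, bh_adjust: bool = False,
                 search: np.ndarray | None = None):
        self.coverage = coverage
        self.annotation = annotation
        self.design = design
        self.params = dict(delta_cut=delta_cut, p_cut=p_cut, min_coverage=min_coverage,
                           coverage_window=coverage_window,
                           min_group_frac=min_group_frac, min_per_group=min_per_group,
                           bh_adjust=bh_adjust)
        self.search = search

    def _passes_group_filter(self, profiles: Mapping[str, np.ndarray]) -> bool:
        floor = self.params["min_coverage"]
        frac = self.params["min_group_frac"]
        window = self.params["coverage_window"]
        for grp in (self.design.case_samples, self.design.control_samples):
            ok = sum(1 for s in grp
                     if s in profiles and proximal_depth(profiles[s], window) >= floor)
            if ok < math.ceil(frac * len(grp)):
                return False
        return True

    def fit(self) -> APAResults:
        samples = self.design.samples
        genes = sorted(self.coverage)
        usage = pd.DataFrame(np.nan, index=pd.Index(genes, name="gene_id"), columns=samples)
        fits: dict[str, TwoIsoformFit] = {}
        for gene in genes:
            profiles = self.coverage[gene]
            if not self._passes_group_filter(profiles):
                fits[gene] = TwoIsoformFit(gene, None, qc_flag="low_coverage")
                continue
            fit = fit_joint_breakpoint(profiles, gene_id=gene, search=self.search,
                                       min_coverage=self.params["min_coverage"],
                                       coverage_window=self.params["coverage_window"])
            fits[gene] = fit
            if fit.breakpoint is None:
                continue
            for s in fit.samples_used:
                usage.loc[gene, s] = compute_pdui(fit.long_abundance[s],
                                                  fit.short_abundance[s])
        table = call_apa_events(usage, self.design,
                                delta_cut=self.params["delta_cut"],
                                p_cut=self.params["p_cut"],
                                min_per_group=self.params["min_per_group"],
                                bh_adjust=self.params["bh_adjust"])
        table.insert(0, "breakpoint",
                     [fits[g].breakpoint if fits[g].breakpoint is not None else np.nan
                      for g in table.index])
        table["qc_flag"] = [fits[g].qc_flag for g in table.index]
        return APAResults(usage, table, "PDUI", self.design, self.params, fits=fits)
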