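"""Shared statistical primitives: rank-sum testing and BH FDR."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

# Exact null enumeration is used for untied samples up to this per-group size;
# beyond it the normal approximation with tie correction applies.
EXACT_MAX_N = 10


def rank_sum_test(x, y, exact_max_n: int = EXACT_MAX_N) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact enumeration for small untied samples, otherwise the tie-corrected
    normal approximation with continuity correction.  Returns NaN when either
    sample is empty or both are constant and equal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        return float("nan")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(x.size, y.size) <= exact_max_n) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs pass through as NaN."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
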