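"""Shared statistical primitives: Mann-Whitney wrapper and BH adjustment."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["mann_whitney", "bh_adjust"]


def mann_whitney(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when both samples have at most ``exact_max_n``
    observations and no ties span the groups; otherwise the tie-corrected
    normal approximation with continuity correction.

    Returns
    -------
    (U, p)
        The U statistic for the first sample and the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= exact_max_n and y.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
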