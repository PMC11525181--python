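"""Shared statistical helpers (paired Wilcoxon wrapper, BH adjustment)."""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_WILCOXON_MAX_N = 24  # exact null distribution below this many pairs


def wilcoxon_paired(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> float:
    """Paired Wilcoxon signed-rank p-value, robust to degenerate input.

    Uses the exact null distribution for fewer than 25 non-tied pairs and
    the normal approximation otherwise.  All-tied input (every difference
    zero) yields p = 1 by convention: there is no evidence of asymmetry.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diffs = x - y
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 1.0
    method = "exact" if nonzero.size <= EXACT_WILCOXON_MAX_N else "approx"
    with warnings.catch_warnings():
        # scipy falls back to the normal approximation on ties; the warning
        # is expected with integer depth data
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(
            x, y, zero_method="wilcox", alternative=alternative, method=method
        )
    return float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (empty-safe)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
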