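"""Shared statistical primitives: one-sided Fisher enrichment p and BH.

The enrichment p-value for a 2x2 presence table is the upper hypergeometric
tail P(X >= n11) with X ~ Hypergeom(N, K_a, K_b) — identical to a one-sided
(greater) Fisher exact test. Vectorized over many tables at once, which the
all-pairs and receptor-x-panel scans rely on.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def fisher_enrichment_p(
    n11: np.ndarray, k_a: np.ndarray, k_b: np.ndarray, n: int
) -> np.ndarray:
    """One-sided (enrichment) Fisher p for 2x2 tables, vectorized.

    Parameters are the overlap count, the two marginal presence counts, and
    the universe size N. Returns P(X >= n11) under the hypergeometric null.
    """
    n11 = np.asarray(n11, dtype=np.int64)
    k_a = np.asarray(k_a, dtype=np.int64)
    k_b = np.asarray(k_b, dtype=np.int64)
    # sf(k) = P(X > k), so sf(n11 - 1) = P(X >= n11)
    p = stats.hypergeom.sf(n11 - 1, n, k_a, k_b)
    return np.clip(p, 0.0, 1.0)


def fisher_two_sided_p(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-sided Fisher exact p for a single table (non-vectorized)."""
    return float(stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")[1])


def odds_ratio(n11: int, n10: int, n01: int, n00: int) -> float:
    """Sample odds ratio with the conventions used throughout the pipeline.

    Infinite when the denominator vanishes but the overlap is non-empty;
    NaN when both numerator cells and the denominator are uninformative.
    """
    denom = n10 * n01
    if denom == 0:
        if n11 > 0 and n00 >= 0:
            return float("inf")
        return float("nan")
    return (n11 * n00) / denom


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    flat = p.ravel()
    adjusted = multipletests(flat, method="fdr_bh")[1]
    return adjusted.reshape(p.shape)
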