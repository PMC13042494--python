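"""Small self-contained statistics used around the concordance analysis.

One-sided hypergeometric gene-set overlap, the exact small-sample
Mann-Whitney U test, and Benjamini-Hochberg adjustment (the latter used by
the synthetic-data generator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class OverlapTest:
    """Result of a one-sided (enrichment) hypergeometric overlap test."""

    k: int
    n1: int
    n2: int
    universe: int
    p: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n1, self.n2)):
            raise ValueError("overlap k must satisfy 0 <= k <= min(n1, n2)")
        if self.n1 > self.universe or self.n2 > self.universe:
            raise ValueError("set sizes cannot exceed the universe")


def hypergeom_overlap(k: int, n1: int, n2: int, universe: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(universe, n1, n2).

    The enrichment ("greater") alternative for the overlap of two gene
    sets of sizes n1 and n2 drawn from a background of ``universe`` genes.
    Computed with scipy's log-gamma-based survival function, so it stays
    finite for universes of ~10^4 genes.
    """
    OverlapTest(k, n1, n2, universe, p=1.0)  # reuse invariant checks
    return float(sps.hypergeom.sf(k - 1, universe, n1, n2))


def overlap_test(k: int, n1: int, n2: int, universe: int) -> OverlapTest:
    return OverlapTest(k, n1, n2, universe, hypergeom_overlap(k, n1, n2, universe))


def mannwhitney_exact(
    x: Sequence[float], y: Sequence[float], two_sided: str = "double_min"
) -> float:
    """Exact two-sided Mann-Whitney U p-value for small untied samples.

    The null enumerates all C(n1+n2, n1) rank assignments.  With
    ``two_sided="double_min"`` (default) p = 2*min(P(U <= u), P(U >= u)),
    capped at 1; ``"both_tails"`` sums both tails at least as extreme as u.
    With no ties the null distribution of U is symmetric, so the two
    definitions coincide.  Ties across groups are rejected: the exact
    enumeration assumes distinct values.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.unique(np.r_[x, y]).size < x.size + y.size:
        raise ValueError("tied values; the exact test requires distinct values")
    if two_sided not in ("double_min", "both_tails"):
        raise ValueError(f"unknown two_sided rule: {two_sided!r}")
    p_less = sps.mannwhitneyu(x, y, alternative="less", method="exact").pvalue
    p_greater = sps.mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
    # both_tails: the opposite tail is P(U >= n1*n2 - u), which equals the
    # observed tail by the symmetry of the untied U null, so both rules
    # reduce to twice the smaller one-sided tail
    return float(min(1.0, 2.0 * min(p_less, p_greater)))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(p, float)
    if arr.size == 0:
        return arr
    if not np.isfinite(arr).all() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]
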