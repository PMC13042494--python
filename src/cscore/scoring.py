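"""The C-score: a continuous dual-contrast concordance statistic.

Given per-gene effect sizes ``E1, E2`` (log2 fold changes, or normalized
enrichment scores for pathways) and BH FDRs from two case-vs-control
comparisons, the C-score quantifies whether a gene responds the *same* way
in both comparisons (positive score) or *differently* (negative score):

.. math::

    C = \\text{Magnitude} \\times \\text{Ratio}

with an FDR-derived significance weight

.. math::

    wFDR(q) = \\begin{cases} 1 & q < 0.05 \\\\
              \\log_{10} q \\,/\\, \\log_{10} 0.05 & q \\ge 0.05 \\end{cases}

a weighted effect magnitude
``Magnitude = |E1| * wFDR(q1) + |E2| * wFDR(q2)`` and a direction-sensitive
ratio: ``max(|E1|,|E2|) / (|E1-E2| + 1)`` when the effects agree in sign
(``E1*E2 > 0``) and ``-|E1-E2| / (max(|E1|,|E2|) + 1)`` otherwise.  Genes
with a zero fold change are scored exactly 0 (direction undefined).

Significance comes from a permutation test: each permutation shuffles the
(effect, FDR) row-pairs of each contrast independently across genes and
recomputes all C-scores; the null distribution is the pool of permuted
scores across genes and permutations.  With few genes the pooled null's
support is exactly the n^2 ordered cross-pairs of (contrast-1 row,
contrast-2 row), which ``exact_mode`` enumerates directly.  One-sided
p-values compare each observed score to the tail of its own sign.

:class:`ConcordanceModel` / :class:`ConcordanceResults` wrap these pieces
in a fit-and-inspect interface; the module-level functions are the
building blocks and accept scalars or arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .contrasts import ContrastTable, DualContrast, align_contrasts

__all__ = [
    "Pattern",
    "PermutationConfig",
    "CScoreRecord",
    "wfdr",
    "ratio",
    "magnitude",
    "c_score",
    "score_dual_contrast",
    "permutation_test",
    "classify",
    "ConcordanceModel",
    "ConcordanceResults",
]

ALPHA_FDR = 0.05  # FDR threshold of the wFDR weight's flat branch
_LOG_ALPHA = np.log10(ALPHA_FDR)
_PERM_CHUNK = 256  # permutations scored per vectorized block


class Pattern(str, Enum):
    """Regulation pattern of a gene across the two comparisons."""

    SHARED_UP = "shared_up"
    SHARED_DOWN = "shared_down"
    DIFFERENT = "different"
    ZERO = "zero"
    NOT_SIGNIFICANT = "not_significant"


class CScoreRecord(NamedTuple):
    """Row view of a scored gene (see ``ConcordanceResults.records``)."""

    feature_id: str
    c_score: float
    magnitude: float
    ratio: float
    wfdr1: float
    wfdr2: float
    perm_p: float
    pattern: str


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the permutation significance test.

    ``n_perm_large`` permutations are used when the gene count exceeds
    ``gene_count_threshold`` (defaults 40 000 and 200); otherwise n^2
    permutations.  ``exact_mode`` enumerates all n^2 ordered cross-pairs
    instead of sampling.  ``p_correction="add_one"`` returns
    (count+1)/(N+1), which cannot be 0; ``"raw_frequency"`` is the plain
    tail frequency.  ``tie_policy="inclusive"`` counts null scores equal to
    the observed one as extreme (standard permutation practice; ties have
    probability ~0 on continuous data); ``"strict"`` does not.
    ``pooled=False`` compares each gene only to the null scores drawn at
    its own position (sampled mode only; the per-gene marginal equals the
    pooled support in exact mode).
    """

    n_perm_large: int = 40_000
    gene_count_threshold: int = 200
    exact_mode: bool = False
    seed: int = 0
    p_correction: str = "add_one"
    tie_policy: str = "inclusive"
    pooled: bool = True

    def __post_init__(self) -> None:
        if self.n_perm_large < 1:
            raise ValueError("n_perm_large must be >= 1")
        if self.gene_count_threshold < 1:
            raise ValueError("gene_count_threshold must be >= 1")
        if self.p_correction not in ("add_one", "raw_frequency"):
            raise ValueError(f"unknown p_correction: {self.p_correction!r}")
        if self.tie_policy not in ("inclusive", "strict"):
            raise ValueError(f"unknown tie_policy: {self.tie_policy!r}")

    def n_permutations(self, n_genes: int) -> int:
        """Permutation count rule: 40 000 above the gene threshold, else n^2."""
        if n_genes > self.gene_count_threshold:
            return self.n_perm_large
        return n_genes * n_genes


def _check_fdr(fdr: np.ndarray) -> None:
    if not np.isfinite(fdr).all() or (fdr < 0).any() or (fdr > 1).any():
        raise ValueError("fdr must lie in [0, 1]")


def wfdr(fdr):
    """FDR significance weight: 1 below 0.05, else log10(fdr)/log10(0.05).

    Monotone non-increasing on [0.05, 1], equal to 1 at the threshold from
    both branches and 0 at fdr = 1.  Accepts scalars or arrays; raises on
    values outside [0, 1].
    """
    arr = np.asarray(fdr, dtype=float)
    _check_fdr(arr)
    with np.errstate(divide="ignore"):
        tail = np.log10(np.where(arr > 0, arr, 1.0)) / _LOG_ALPHA
    out = np.where(arr < ALPHA_FDR, 1.0, tail) + 0.0  # normalize -0.0
    return float(out) if np.isscalar(fdr) or arr.ndim == 0 else out


def ratio(e1, e2):
    """Direction-sensitive concordance ratio of two effect sizes.

    Positive iff the effects agree in sign, bounded by max(|e1|, |e2|) in
    absolute value, and 0 when both effects are 0.
    """
    a1 = np.asarray(e1, dtype=float)
    a2 = np.asarray(e2, dtype=float)
    if not (np.isfinite(a1).all() and np.isfinite(a2).all()):
        raise ValueError("effects must be finite")
    big = np.maximum(np.abs(a1), np.abs(a2))
    gap = np.abs(a1 - a2)
    out = np.where(a1 * a2 > 0, big / (gap + 1.0), -gap / (big + 1.0))
    return float(out) if out.ndim == 0 else out


def magnitude(e1, fdr1, e2, fdr2):
    """FDR-weighted effect magnitude |e1|*wfdr(fdr1) + |e2|*wfdr(fdr2) >= 0."""
    out = np.abs(np.asarray(e1, float)) * wfdr(fdr1) + np.abs(np.asarray(e2, float)) * wfdr(fdr2)
    return float(out) if np.ndim(out) == 0 else out


def c_score(e1, fdr1, e2, fdr2, zero_rule: str = "either"):
    """C-score = magnitude * ratio, with the zero-fold-change rule applied.

    ``zero_rule="either"`` (default) scores a gene 0 when either effect is
    exactly 0 — a zero fold change has no direction, so neither branch of
    the ratio applies; ``"both"`` only when both are 0.
    """
    if zero_rule not in ("either", "both"):
        raise ValueError(f"unknown zero_rule: {zero_rule!r}")
    a1 = np.asarray(e1, float)
    a2 = np.asarray(e2, float)
    raw = magnitude(a1, fdr1, a2, fdr2) * ratio(a1, a2)
    zero = (a1 == 0) | (a2 == 0) if zero_rule == "either" else (a1 == 0) & (a2 == 0)
    out = np.where(zero, 0.0, raw)
    return float(out) if out.ndim == 0 else out


def score_dual_contrast(dc: DualContrast, zero_rule: str = "either") -> pd.DataFrame:
    """Score every feature of a :class:`DualContrast`.

    Returns one row per feature, in ``dc.features`` order, with columns
    feature, e1, fdr1, e2, fdr2, wfdr1, wfdr2, magnitude, ratio, c_score,
    and unset (NaN) perm_p / empty pattern to be filled by
    :func:`permutation_test` and :func:`classify`.
    """
    df = dc.to_frame()
    df["wfdr1"] = wfdr(dc.fdr1)
    df["wfdr2"] = wfdr(dc.fdr2)
    df["magnitude"] = magnitude(dc.e1, dc.fdr1, dc.e2, dc.fdr2)
    df["ratio"] = ratio(dc.e1, dc.e2)
    df["c_score"] = c_score(dc.e1, dc.fdr1, dc.e2, dc.fdr2, zero_rule=zero_rule)
    df["perm_p"] = np.nan
    df["pattern"] = ""
    return df


def _tail_counts_pooled(null_sorted: np.ndarray, observed: np.ndarray):
    """Counts of pooled null values <=, <, >=, > each observed value."""
    le = np.searchsorted(null_sorted, observed, side="right")
    lt = np.searchsorted(null_sorted, observed, side="left")
    n = len(null_sorted)
    return le, lt, n - lt, n - le


def _pvalues_from_counts(observed, lo_count, hi_count, n_null, cfg: PermutationConfig):
    """One-sided p per gene: upper tail for positive scores, lower for negative."""
    count = np.where(observed > 0, hi_count, lo_count)
    if cfg.p_correction == "add_one":
        p = (count + 1.0) / (n_null + 1.0)
    else:
        p = count / float(n_null)
    return np.where(observed == 0, 1.0, np.minimum(p, 1.0))


def permutation_test(
    dc: DualContrast,
    scores: pd.DataFrame,
    cfg: PermutationConfig | None = None,
    zero_rule: str = "either",
) -> pd.DataFrame:
    """Fill ``perm_p`` of a scored table via the cross-pairing null.

    Null model: each permutation shuffles the (effect, FDR) row-pairs of
    contrast 1 and of contrast 2 independently across genes (an effect
    stays glued to its own FDR), recomputes C-scores, and all permuted
    scores are pooled into one null distribution — equivalently, sampling
    scores C(E1_i, FDR1_i, E2_j, FDR2_j) over ordered cross-pairs (i, j).
    ``cfg.exact_mode`` enumerates the n^2 cross-pairs instead.  For each
    gene the one-sided p is the null-tail frequency beyond the observed
    score on its own side; zero-scored genes get p = 1.
    """
    cfg = cfg or PermutationConfig()
    n = len(dc)
    if n < 2:
        raise ValueError("permutation test needs at least 2 genes")
    observed = scores["c_score"].to_numpy(float)
    if len(observed) != n:
        raise ValueError("scores do not correspond to the DualContrast")

    if cfg.exact_mode:
        null = c_score(
            dc.e1[:, None], dc.fdr1[:, None], dc.e2[None, :], dc.fdr2[None, :],
            zero_rule=zero_rule,
        ).ravel()
        null.sort()
        le, lt, ge, gt = _tail_counts_pooled(null, observed)
        hi = gt if cfg.tie_policy == "strict" else ge
        lo = lt if cfg.tie_policy == "strict" else le
        p = _pvalues_from_counts(observed, lo, hi, null.size, cfg)
    else:
        rng = np.random.default_rng(cfg.seed)
        n_perm = cfg.n_permutations(n)
        base = np.arange(n)
        lo_c = np.zeros(n, dtype=np.int64)
        hi_c = np.zeros(n, dtype=np.int64)
        done = 0
        while done < n_perm:
            m = min(_PERM_CHUNK, n_perm - done)
            # one generator, contrast-1 block then contrast-2 block per chunk
            idx1 = rng.permuted(np.broadcast_to(base, (m, n)), axis=1)
            idx2 = rng.permuted(np.broadcast_to(base, (m, n)), axis=1)
            null = c_score(
                dc.e1[idx1], dc.fdr1[idx1], dc.e2[idx2], dc.fdr2[idx2],
                zero_rule=zero_rule,
            )
            if cfg.pooled:
                flat = null.ravel()
                flat.sort()
                le, lt, ge, gt = _tail_counts_pooled(flat, observed)
                lo_c += lt if cfg.tie_policy == "strict" else le
                hi_c += gt if cfg.tie_policy == "strict" else ge
            else:
                if cfg.tie_policy == "strict":
                    lo_c += (null < observed).sum(axis=0)
                    hi_c += (null > observed).sum(axis=0)
                else:
                    lo_c += (null <= observed).sum(axis=0)
                    hi_c += (null >= observed).sum(axis=0)
            done += m
        n_null = n_perm * n if cfg.pooled else n_perm
        p = _pvalues_from_counts(observed, lo_c, hi_c, n_null, cfg)

    out = scores.copy()
    out["perm_p"] = p
    return out


def classify(
    scores: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Assign the regulation pattern from score, sign and permutation p.

    zero if c = 0; not_significant if perm_p >= alpha; otherwise shared_up
    (c > 0, e1 > 0), shared_down (c > 0, e1 < 0) or different (c < 0).
    """
    c = scores["c_score"].to_numpy(float)
    p = scores["perm_p"].to_numpy(float)
    if np.isnan(p).any():
        raise ValueError("perm_p not populated; run permutation_test first")
    e1 = scores["e1"].to_numpy(float)
    pattern = np.where(
        c == 0,
        Pattern.ZERO.value,
        np.where(
            p >= alpha,
            Pattern.NOT_SIGNIFICANT.value,
            np.where(
                c < 0,
                Pattern.DIFFERENT.value,
                np.where(e1 > 0, Pattern.SHARED_UP.value, Pattern.SHARED_DOWN.value),
            ),
        ),
    )
    out = scores.copy()
    out["pattern"] = pattern
    return out


class ConcordanceModel:
    """Dual-contrast concordance model for one cell type.

    Built from a :class:`DualContrast` (or two contrast tables, or a plain
    DataFrame); ``fit`` runs scoring, the permutation test and pattern
    classification and returns a :class:`ConcordanceResults`.

    Parameters
    ----------
    dual_contrast
        Aligned effects and FDRs of the two comparisons.
    zero_rule
        ``"either"`` (default) or ``"both"``: when the zero-fold-change
        rule forces a score of exactly 0.
    """

    def __init__(self, dual_contrast: DualContrast, zero_rule: str = "either"):
        if zero_rule not in ("either", "both"):
            raise ValueError(f"unknown zero_rule: {zero_rule!r}")
        self.dual_contrast = dual_contrast
        self.zero_rule = zero_rule

    @classmethod
    def from_tables(
        cls, a: ContrastTable, b: ContrastTable, zero_rule: str = "either", **align_kw
    ) -> "ConcordanceModel":
        return cls(align_contrasts(a, b, **align_kw), zero_rule=zero_rule)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, cell_type: str = "", zero_rule: str = "either"
    ) -> "ConcordanceModel":
        """Build from a frame with columns feature, e1, fdr1, e2, fdr2."""
        return cls(DualContrast.from_frame(df, cell_type=cell_type), zero_rule=zero_rule)

    @property
    def nobs(self) -> int:
        return len(self.dual_contrast)

    def fit(
        self,
        permutation: PermutationConfig | None = None,
        alpha: float = 0.05,
        seed: int | None = None,
    ) -> "ConcordanceResults":
        """Score all genes, compute permutation p-values and classify.

        ``seed`` overrides the seed inside ``permutation`` for convenience.
        ``alpha`` is the one-sided significance level of the pattern call.
        """
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        cfg = permutation or PermutationConfig()
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        frame = score_dual_contrast(self.dual_contrast, zero_rule=self.zero_rule)
        frame = permutation_test(self.dual_contrast, frame, cfg, zero_rule=self.zero_rule)
        frame = classify(frame, alpha=alpha)
        return ConcordanceResults(self, frame, cfg, alpha)


class ConcordanceResults:
    """Fitted concordance analysis: per-gene scores, p-values and patterns."""

    def __init__(
        self,
        model: ConcordanceModel,
        frame: pd.DataFrame,
        permutation: PermutationConfig,
        alpha: float,
    ):
        self.model = model
        self.frame = frame
        self.permutation = permutation
        self.alpha = alpha

    # -- accessors -------------------------------------------------------
    @property
    def nobs(self) -> int:
        return len(self.frame)

    @property
    def c_scores(self) -> pd.Series:
        return self.frame.set_index("feature")["c_score"]

    @property
    def perm_pvalues(self) -> pd.Series:
        return self.frame.set_index("feature")["perm_p"]

    @property
    def patterns(self) -> pd.Series:
        return self.frame.set_index("feature")["pattern"]

    @property
    def records(self) -> list[CScoreRecord]:
        return [
            CScoreRecord(
                r.feature, r.c_score, r.magnitude, r.ratio,
                r.wfdr1, r.wfdr2, r.perm_p, r.pattern,
            )
            for r in self.frame.itertuples(index=False)
        ]

    def pattern_counts(self) -> pd.Series:
        counts = self.frame["pattern"].value_counts()
        return counts.reindex([p.value for p in Pattern], fill_value=0)

    def significant(self) -> pd.DataFrame:
        """Rows called shared or different at the fitted alpha."""
        keep = self.frame["pattern"].isin(
            [Pattern.SHARED_UP.value, Pattern.SHARED_DOWN.value, Pattern.DIFFERENT.value]
        )
        return self.frame[keep]

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.17g")

    # -- reporting -------------------------------------------------------
    def summary(self, top: int = 5) -> str:
        """Plain-text summary: fit settings, pattern counts, extreme genes."""
        dc = self.model.dual_contrast
        counts = self.pattern_counts()
        lines = [
            "Dual-contrast concordance (C-score) results",
            "=" * 47,
            f"cell type:        {dc.cell_type or '<unnamed>'}",
            f"contrasts:        {dc.contrast_labels[0]} / {dc.contrast_labels[1]}",
            f"genes scored:     {self.nobs}",
            f"permutations:     {self.permutation.n_permutations(self.nobs)}"
            + (" (exact cross-pair enumeration)" if self.permutation.exact_mode else ""),
            f"alpha (one-sided):{self.alpha:>7}",
            "",
            "pattern counts:",
        ]
        for name, cnt in counts.items():
            lines.append(f"  {name:<16}{cnt:>7}")
        srt = self.frame.sort_values("c_score")
        lines.append("")
        lines.append(f"top {top} concordant (highest C):")
        for r in srt.tail(top).iloc[::-1].itertuples(index=False):
            lines.append(f"  {r.feature:<14} C={r.c_score:+.3f}  p={r.perm_p:.4g}")
        lines.append(f"top {top} discordant (lowest C):")
        for r in srt.head(top).itertuples(index=False):
            lines.append(f"  {r.feature:<14} C={r.c_score:+.3f}  p={r.perm_p:.4g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Rank-ordered C-score scatter, colored by pattern call."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        srt = self.frame.sort_values("c_score").reset_index(drop=True)
        colors = {
            Pattern.SHARED_UP.value: "#c0392b",
            Pattern.SHARED_DOWN.value: "#2980b9",
            Pattern.DIFFERENT.value: "#8e44ad",
            Pattern.ZERO.value: "#bdc3c7",
            Pattern.NOT_SIGNIFICANT.value: "#7f8c8d",
        }
        for name, grp in srt.groupby("pattern"):
            ax.scatter(grp.index, grp["c_score"], s=8, label=name,
                       color=colors.get(name, "k"), alpha=0.7)
        ax.axhline(0.0, lw=0.8, color="k")
        ax.set_xlabel("gene rank by C-score")
        ax.set_ylabel("C-score")
        ax.set_title(self.model.dual_contrast.cell_type or "concordance")
        ax.legend(fontsize=7, frameon=False)
        return ax
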