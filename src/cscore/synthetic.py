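"""Synthetic dual-contrast benchmarks with planted ground truth.

Emulates the statistical structure the concordance analysis consumes: per
gene, two observed log2 fold changes with BH FDRs, where a known fraction
of genes is planted as shared-up, shared-down, differently regulated or
null.  True effects live on the log2 scale directly (the C-score consumes
only effect + FDR, so count-level realism would add nothing testable);
observed effects add Gaussian estimation noise, per-gene p-values come
from the corresponding z-test and are BH-adjusted within each contrast.

Also provides a toy ligand-receptor resource and a multi-cell-type scored
fixture so the communication-network stage is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .contrasts import DualContrast
from .network import LRPair
from .scoring import ConcordanceModel, ConcordanceResults, PermutationConfig
from .stats import bh_adjust

CLASSES = ("shared_up", "shared_down", "different", "null")

#: per-stage additive seed offsets, fixed so all fixtures are reproducible
SEED_OFFSET_CELLTYPE = 1  # cell type i draws with seed + i
SEED_OFFSET_RESOURCE = 10_000


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic benchmark.

    Defaults are a sparse-signal regime: 2 000 genes of which 15% carry a
    planted signal (5% shared-up, 5% shared-down, 5% different), true
    absolute effects ~ Normal(1.5, 0.3) truncated at 0 on the log2 scale
    (clear but not extreme DE), and an observed-effect standard error of
    0.25 (well-powered per-gene estimates, as in a moderately sized
    pseudobulk comparison).
    """

    n_genes: int = 2_000
    proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "shared_up": 0.05, "shared_down": 0.05, "different": 0.05, "null": 0.85,
        }
    )
    effect_mean: float = 1.5
    effect_sd: float = 0.3
    noise_se: float = 0.25
    seed: int = 0
    n_cell_types: int = 3
    lr_n_pairs: int = 25
    lr_complex_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if set(self.proportions) != set(CLASSES):
            raise ValueError(f"proportions must have keys {CLASSES}")
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if min(self.proportions.values()) < 0:
            raise ValueError("proportions must be non-negative")
        if self.effect_sd <= 0 or self.noise_se <= 0:
            raise ValueError("effect_sd and noise_se must be > 0")
        if not 0 <= self.lr_complex_fraction <= 1:
            raise ValueError("lr_complex_fraction must be in [0, 1]")


def _truncated_abs_effect(rng: np.random.Generator, size: int, cfg: SyntheticConfig):
    """|theta| ~ Normal(effect_mean, effect_sd) truncated at 0 (resampled)."""
    out = rng.normal(cfg.effect_mean, cfg.effect_sd, size)
    while (out <= 0).any():
        bad = out <= 0
        out[bad] = rng.normal(cfg.effect_mean, cfg.effect_sd, int(bad.sum()))
    return out


def generate_dual_contrast(
    cfg: SyntheticConfig, seed: int | None = None
) -> tuple[DualContrast, pd.DataFrame]:
    """Generate one aligned dual contrast plus its planted truth table.

    Per gene the class is drawn from ``cfg.proportions``.  Shared genes get
    a common random sign and independent truncated-normal magnitudes per
    contrast; different genes get opposite signs with the same magnitude
    law; null genes have zero true effect.  Observed effects are
    truth + Normal(0, noise_se); FDRs are BH-adjusted two-sided z-test
    p-values within each contrast.  Deterministic given the seed.

    Returns the :class:`DualContrast` and a truth DataFrame with columns
    feature, true_class, theta1, theta2 (same lexicographic gene order).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_genes
    width = len(str(n))
    features = np.array([f"gene{i:0{width}d}" for i in range(1, n + 1)])

    probs = [cfg.proportions[c] for c in CLASSES]
    classes = rng.choice(len(CLASSES), size=n, p=probs)
    theta1 = np.zeros(n)
    theta2 = np.zeros(n)
    signal = classes != CLASSES.index("null")
    m1 = _truncated_abs_effect(rng, int(signal.sum()), cfg)
    m2 = _truncated_abs_effect(rng, int(signal.sum()), cfg)
    sig_idx = np.flatnonzero(signal)
    for j, g in enumerate(sig_idx):
        cls = CLASSES[classes[g]]
        if cls == "shared_up":
            s = 1.0
        elif cls == "shared_down":
            s = -1.0
        else:  # different: random common sign, flipped in contrast 2
            s = rng.choice([-1.0, 1.0])
        theta1[g] = s * m1[j]
        theta2[g] = (s if cls != "different" else -s) * m2[j]

    e1 = theta1 + rng.normal(0.0, cfg.noise_se, n)
    e2 = theta2 + rng.normal(0.0, cfg.noise_se, n)
    p1 = 2.0 * sps.norm.sf(np.abs(e1) / cfg.noise_se)
    p2 = 2.0 * sps.norm.sf(np.abs(e2) / cfg.noise_se)
    dual = DualContrast(
        cell_type="synthetic",
        features=features,
        e1=e1, fdr1=bh_adjust(p1), e2=e2, fdr2=bh_adjust(p2),
        contrast_labels=("sim_contrast1", "sim_contrast2"),
    )
    truth = pd.DataFrame(
        {
            "feature": features,
            "true_class": [CLASSES[c] for c in classes],
            "theta1": theta1,
            "theta2": theta2,
        }
    )
    return dual, truth


def generate_lr_resource(
    cfg: SyntheticConfig, gene_pool, seed: int | None = None
) -> list[LRPair]:
    """Sample a toy ligand-receptor resource from a gene pool.

    Draws ``lr_n_pairs`` pairs; genes are taken without replacement while
    the pool lasts, then with replacement.  A ``lr_complex_fraction`` of
    pairs (randomly chosen, exact count) get a 2-subunit receptor complex.
    """
    gene_pool = list(gene_pool)
    if len(gene_pool) < 4:
        raise ValueError("gene pool too small (need >= 4 genes)")
    rng = np.random.default_rng(
        (cfg.seed if seed is None else seed) + SEED_OFFSET_RESOURCE
    )
    n_complex = int(round(cfg.lr_complex_fraction * cfg.lr_n_pairs))
    is_complex = np.zeros(cfg.lr_n_pairs, dtype=bool)
    is_complex[rng.choice(cfg.lr_n_pairs, size=n_complex, replace=False)] = True
    need = int(cfg.lr_n_pairs + (cfg.lr_n_pairs + n_complex))
    if need <= len(gene_pool):
        drawn = list(rng.choice(gene_pool, size=need, replace=False))
    else:
        drawn = list(rng.choice(gene_pool, size=len(gene_pool), replace=False))
        drawn += list(rng.choice(gene_pool, size=need - len(gene_pool), replace=True))
    pairs = []
    pos = 0
    for i in range(cfg.lr_n_pairs):
        lig = (drawn[pos],)
        pos += 1
        if is_complex[i]:
            rec = (drawn[pos], drawn[pos + 1])
            pos += 2
        else:
            rec = (drawn[pos],)
            pos += 1
        pairs.append(LRPair("_".join(lig) + "->" + "_".join(rec), lig, rec))
    return pairs


def generate_multi_celltype_scores(
    cfg: SyntheticConfig,
    permutation: PermutationConfig | None = None,
    alpha: float = 0.05,
) -> dict[str, tuple[ConcordanceResults, pd.DataFrame]]:
    """Independent scored dual contrasts for ``cfg.n_cell_types`` cell types.

    Cell type ``CT{i}`` is generated with seed ``cfg.seed + i`` (the fixed
    per-cell-type offset) and pushed through the full concordance fit, so
    the output feeds the communication-network stage directly.
    """
    out: dict[str, tuple[ConcordanceResults, pd.DataFrame]] = {}
    for i in range(1, cfg.n_cell_types + 1):
        seed = cfg.seed + i * SEED_OFFSET_CELLTYPE
        dual, truth = generate_dual_contrast(cfg, seed=seed)
        dual = replace(dual, cell_type=f"CT{i}")
        perm = permutation or PermutationConfig(seed=seed)
        res = ConcordanceModel(dual).fit(permutation=perm, alpha=alpha, seed=seed)
        out[f"CT{i}"] = (res, truth)
    return out
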