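"""End-to-end orchestration: align -> score -> permute -> classify -> network.

Driven by a single YAML/JSON-compatible config (:class:`RunConfig`); writes
per-cell-type score tables, sign-split edge lists, degree tables, a
machine-readable run summary and a dropped-records audit into the output
directory.  Deterministic given the config (including the seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .contrasts import align_contrasts, read_contrast_table
from .network import build_network, degrees, rank_genes, read_lr_resource, split_by_sign
from .scoring import ConcordanceModel, PermutationConfig
from .stats import OverlapTest, overlap_test

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


@dataclass(frozen=True)
class RunConfig:
    """Single source of truth for a full pipeline run.

    ``contrasts`` maps each cell type to the two contrast-table paths
    (comparison 1, comparison 2).  Network flags mirror
    :func:`cscore.network.build_network`.
    """

    contrasts: Mapping[str, Sequence[str]]
    resource: str
    output_dir: str
    alpha: float = 0.05
    seed: int = 0
    zero_rule: str = "either"
    n_perm_large: int = 40_000
    gene_count_threshold: int = 200
    exact_mode: bool = False
    p_correction: str = "add_one"
    tie_policy: str = "inclusive"
    subunit_agg: str = "sum"
    require_all_subunits: bool = False
    include_self_edges: bool = False
    max_mean_p: float | None = None
    column_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.contrasts:
            raise ValueError("no contrasts configured")
        for ct, paths in self.contrasts.items():
            if len(paths) != 2:
                raise ValueError(f"cell type {ct!r} needs exactly 2 contrast paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def permutation_config(self) -> PermutationConfig:
        return PermutationConfig(
            n_perm_large=self.n_perm_large,
            gene_count_threshold=self.gene_count_threshold,
            exact_mode=self.exact_mode,
            seed=self.seed,
            p_correction=self.p_correction,
            tie_policy=self.tie_policy,
        )


@dataclass(frozen=True)
class RunSummary:
    """Machine-readable outcome of one pipeline run."""

    pattern_counts: Mapping[str, Mapping[str, int]]
    n_genes: Mapping[str, int]
    edge_counts: Mapping[str, int]
    degree_tables: Mapping[str, list]
    seed: int
    version: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage label
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> RunSummary:
    """Run the full analysis described by ``config``.

    Stages: read + align each cell type's contrast pair, fit the
    concordance model (scores, permutation p, patterns), build the
    ligand-receptor network, split it by sign, compute degree tables and
    gene rankings.  All outputs land in ``config.output_dir``; every
    dropped gene or edge is recorded in ``dropped_records.tsv``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "scores").mkdir(exist_ok=True)
    with open(out_dir / "config_effective.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    dropped: list[dict] = []
    results = {}
    pattern_counts = {}
    n_genes = {}

    @_stage("contrasts")
    def _load(ct: str, p1: str, p2: str):
        a = read_contrast_table(p1, cell_type=ct, column_map=config.column_map or None)
        b = read_contrast_table(p2, cell_type=ct, column_map=config.column_map or None)
        dual = align_contrasts(a, b)
        for side, table in (("contrast1", a), ("contrast2", b)):
            lost = set(table.feature_ids) - set(dual.features)
            for g in sorted(lost):
                dropped.append({"stage": "align", "cell_type": ct,
                                "record": g, "reason": f"absent from other table ({side})"})
        return dual

    @_stage("cscore")
    def _fit(dual):
        model = ConcordanceModel(dual, zero_rule=config.zero_rule)
        return model.fit(permutation=config.permutation_config(), alpha=config.alpha)

    for ct in sorted(config.contrasts):
        p1, p2 = config.contrasts[ct]
        logger.info("scoring cell type %s", ct)
        dual = _load(ct, p1, p2)
        res = _fit(dual)
        res.write_tsv(out_dir / "scores" / f"{ct}.tsv")
        results[ct] = res
        pattern_counts[ct] = {k: int(v) for k, v in res.pattern_counts().items()}
        n_genes[ct] = res.nobs
        for g in res.frame.loc[res.frame["c_score"] == 0, "feature"]:
            dropped.append({"stage": "cscore", "cell_type": ct,
                            "record": g, "reason": "zero-fold-change rule"})

    @_stage("network")
    def _network():
        resource = read_lr_resource(config.resource)
        net = build_network(
            results, resource,
            include_self_edges=config.include_self_edges,
            subunit_agg=config.subunit_agg,
            require_all_subunits=config.require_all_subunits,
            max_mean_p=config.max_mean_p,
        )
        return net, split_by_sign(net)

    net, split = _network()
    for g in range(split.n_zero_dropped):
        dropped.append({"stage": "network", "cell_type": "",
                        "record": f"zero-weight-edge-{g}", "reason": "zero edge weight"})

    degree_tables = {}
    for label, subnet in (("full", net), ("shared", split.shared),
                          ("different", split.different)):
        subnet.write_tsv(out_dir / f"network_{label}.tsv")
        deg = degrees(subnet)
        deg.to_csv(out_dir / f"degrees_{label}.tsv", sep="\t", index=False)
        degree_tables[label] = deg.to_dict(orient="records")
    for role in ("ligand", "receptor"):
        rank_genes(net, role).to_csv(out_dir / f"rank_{role}s.tsv", sep="\t", index=False)

    pd.DataFrame(dropped, columns=["stage", "cell_type", "record", "reason"]).to_csv(
        out_dir / "dropped_records.tsv", sep="\t", index=False
    )
    summary = RunSummary(
        pattern_counts=pattern_counts,
        n_genes=n_genes,
        edge_counts={
            "full": len(net),
            "shared": len(split.shared),
            "different": len(split.different),
            "zero_dropped": split.n_zero_dropped,
        },
        degree_tables=degree_tables,
        seed=config.seed,
        version=__version__,
    )
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        fh.write(summary.to_json())
    return summary


def compare_gene_sets(set_a, set_b, universe: int) -> OverlapTest:
    """Hypergeometric enrichment test of the overlap of two gene sets."""
    sa, sb = set(set_a), set(set_b)
    if len(sa) > universe or len(sb) > universe:
        raise ValueError("gene set larger than the declared universe")
    return overlap_test(len(sa & sb), len(sa), len(sb), universe)
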