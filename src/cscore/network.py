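"""C-score-weighted ligand-receptor cell-cell communication networks.

Each directed edge is a (sender cell type, receiver cell type, ligand,
receptor) tetramer: the ligand subunits are looked up in the sender's
scored gene table, the receptor subunits in the receiver's, the edge
weight is the sum of the found genes' C-scores and the edge carries the
arithmetic mean of their permutation p-values.  Positive-weight edges form
the "shared" regulation network, negative-weight edges the "different"
one; per-cell-type in/out-degrees are sums of absolute edge weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LRPair:
    """A ligand-receptor pair; either side may be a multi-subunit complex."""

    name: str
    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ligand_subunits or not self.receptor_subunits:
            raise ValueError(f"LRPair {self.name!r}: subunit lists must be non-empty")


@dataclass(frozen=True)
class CCCEdge:
    """One sender->receiver tetramer with its summed-C weight and mean p."""

    sender: str
    receiver: str
    pair: LRPair
    weight: float
    mean_p: float
    n_genes_contributing: int

    def __post_init__(self) -> None:
        if self.n_genes_contributing < 1:
            raise ValueError("edge with no contributing genes")
        if not np.isfinite(self.weight):
            raise ValueError("edge weight must be finite")


@dataclass(frozen=True)
class CCCNetwork:
    """Directed multigraph of tetramer edges over a set of cell types."""

    edges: tuple[CCCEdge, ...]
    cell_types: frozenset[str]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e.sender not in self.cell_types or e.receiver not in self.cell_types:
                raise ValueError(f"edge {e.sender}->{e.receiver} uses unknown cell type")
            key = (e.sender, e.receiver, e.pair.name)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sender": e.sender,
                    "receiver": e.receiver,
                    "pair": e.pair.name,
                    "ligand": "_".join(e.pair.ligand_subunits),
                    "receptor": "_".join(e.pair.receptor_subunits),
                    "weight": e.weight,
                    "mean_p": e.mean_p,
                    "n_genes": e.n_genes_contributing,
                }
                for e in self.edges
            ],
            columns=["sender", "receiver", "pair", "ligand", "receptor",
                     "weight", "mean_p", "n_genes"],
        )

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(sorted(self.cell_types))
        for e in self.edges:
            g.add_edge(e.sender, e.receiver, key=e.pair.name,
                       weight=e.weight, abs_weight=abs(e.weight),
                       mean_p=e.mean_p, n_genes=e.n_genes_contributing)
        return g

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_lr_resource(path: str | Path, sep: str | None = None) -> list[LRPair]:
    """Read a ligand-receptor resource CSV/TSV.

    Expected columns ``pair_name``, ``ligand``, ``receptor``; complex
    subunits joined by ``_`` (e.g. ``ITGA3_ITGB1``), the convention of
    LIANA/CellPhoneDB-style consensus resources.
    """
    path = Path(path)
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            sep = "\t" if "\t" in fh.readline() else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"pair_name", "ligand", "receptor"} - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: resource missing columns {sorted(missing)}")
    pairs = [
        LRPair(r.pair_name, tuple(r.ligand.split("_")), tuple(r.receptor.split("_")))
        for r in df.itertuples(index=False)
    ]
    names = [p.name for p in pairs]
    if len(set(names)) != len(names):
        raise ValueError(f"{path.name}: duplicate pair names")
    return pairs


def write_lr_resource(pairs: Sequence[LRPair], path: str | Path) -> None:
    pd.DataFrame(
        {
            "pair_name": [p.name for p in pairs],
            "ligand": ["_".join(p.ligand_subunits) for p in pairs],
            "receptor": ["_".join(p.receptor_subunits) for p in pairs],
        }
    ).to_csv(path, index=False)


def _score_lookup(table) -> dict[str, tuple[float, float]]:
    """gene -> (c_score, perm_p) from a scored frame or ConcordanceResults."""
    frame = table.to_frame() if hasattr(table, "to_frame") else table
    feats = frame["feature"]
    if feats.duplicated().any():
        raise ValueError("gene appearing twice in one score table")
    return dict(zip(feats, zip(frame["c_score"], frame["perm_p"])))


def _aggregate(values: list[float], how: str) -> float:
    if how == "sum":
        return float(np.sum(values))
    if how == "mean":
        return float(np.mean(values))
    if how == "min":
        return float(np.min(values))
    raise ValueError(f"unknown subunit_agg: {how!r}")


def build_network(
    scores_by_celltype: Mapping[str, object],
    resource: Sequence[LRPair],
    include_self_edges: bool = False,
    subunit_agg: str = "sum",
    require_all_subunits: bool = False,
    max_mean_p: float | None = None,
) -> CCCNetwork:
    """Build the tetramer network from per-cell-type C-score tables.

    For every ordered (sender, receiver) cell-type pair and every resource
    pair, ligand subunit scores are taken from the sender's table and
    receptor subunit scores from the receiver's.  An edge is emitted when
    at least one subunit on each side is found (all of them with
    ``require_all_subunits``); missing subunits contribute nothing and are
    counted in the log.  ``subunit_agg`` aggregates the subunit C-scores
    within each side ("sum", "mean" or "min") and the edge weight is the
    ligand aggregate plus the receptor aggregate — for "sum" this is the
    plain sum of C-scores over all found genes.  ``mean_p`` is always the
    arithmetic mean of the found genes' permutation p-values.
    ``max_mean_p`` optionally drops edges above a mean-p cut.
    """
    if not scores_by_celltype:
        raise ValueError("no cell types given")
    if len(scores_by_celltype) < 2 and not include_self_edges:
        raise ValueError("need at least 2 cell types (or include_self_edges=True)")
    if not resource:
        raise ValueError("empty ligand-receptor resource")
    lookups: dict[str, dict[str, tuple[float, float]]] = {}
    for ct in sorted(scores_by_celltype):
        lut = _score_lookup(scores_by_celltype[ct])
        if not lut:
            raise ValueError(f"empty score table for cell type {ct!r}")
        lookups[ct] = lut

    edges: list[CCCEdge] = []
    n_missing_subunits = 0
    cell_types = sorted(lookups)
    for sender in cell_types:
        for receiver in cell_types:
            if sender == receiver and not include_self_edges:
                continue
            for pair in sorted(resource, key=lambda p: p.name):
                lig = [lookups[sender].get(g) for g in pair.ligand_subunits]
                rec = [lookups[receiver].get(g) for g in pair.receptor_subunits]
                lig_found = [v for v in lig if v is not None]
                rec_found = [v for v in rec if v is not None]
                n_missing_subunits += lig.count(None) + rec.count(None)
                if not lig_found or not rec_found:
                    continue
                if require_all_subunits and (None in lig or None in rec):
                    continue
                weight = _aggregate([c for c, _ in lig_found], subunit_agg) + _aggregate(
                    [c for c, _ in rec_found], subunit_agg
                )
                pvals = [p for _, p in lig_found] + [p for _, p in rec_found]
                mean_p = float(np.mean(pvals))
                if max_mean_p is not None and mean_p > max_mean_p:
                    continue
                edges.append(
                    CCCEdge(sender, receiver, pair, weight, mean_p,
                            len(lig_found) + len(rec_found))
                )
    if n_missing_subunits:
        logger.info("build_network: %d subunit lookups missing from score tables",
                    n_missing_subunits)
    return CCCNetwork(tuple(edges), frozenset(cell_types))


class SignSplit(NamedTuple):
    shared: CCCNetwork
    different: CCCNetwork
    n_zero_dropped: int


def split_by_sign(net: CCCNetwork) -> SignSplit:
    """Partition into shared (weight > 0) and different (weight < 0) networks.

    Zero-weight edges belong to neither sign; they are dropped and counted
    in ``n_zero_dropped``.
    """
    shared = tuple(e for e in net.edges if e.weight > 0)
    different = tuple(e for e in net.edges if e.weight < 0)
    n_zero = len(net.edges) - len(shared) - len(different)
    if n_zero:
        logger.info("split_by_sign: dropped %d zero-weight edge(s)", n_zero)
    return SignSplit(
        CCCNetwork(shared, net.cell_types),
        CCCNetwork(different, net.cell_types),
        n_zero,
    )


def degrees(net: CCCNetwork) -> pd.DataFrame:
    """Weighted in/out-degree per cell type, on absolute edge weights.

    out_degree(c) = sum of |weight| over edges sent by c; in_degree(c)
    likewise over edges received.  Cell types without edges get 0.
    Absolute values keep the degrees of the negative-weight "different"
    subnetwork positive and comparable to the shared one.
    """
    g = net.to_networkx()
    out_d = dict(g.out_degree(weight="abs_weight"))
    in_d = dict(g.in_degree(weight="abs_weight"))
    cts = sorted(net.cell_types)
    return pd.DataFrame(
        {
            "cell_type": cts,
            "out_degree": [float(out_d.get(c, 0.0)) for c in cts],
            "in_degree": [float(in_d.get(c, 0.0)) for c in cts],
        }
    )


def rank_genes(net: CCCNetwork, role: str) -> pd.DataFrame:
    """Rank genes by summed |edge weight| in a given role.

    ``role`` is "ligand" (gene counted on the sender side) or "receptor"
    (receiver side); a gene in several edges accumulates their absolute
    weights.  Returns (cell_type, gene, score) sorted by descending score,
    ties broken by gene id.
    """
    if role not in ("ligand", "receptor"):
        raise ValueError(f"role must be 'ligand' or 'receptor', got {role!r}")
    acc: dict[tuple[str, str], float] = {}
    for e in net.edges:
        cell = e.sender if role == "ligand" else e.receiver
        subunits = e.pair.ligand_subunits if role == "ligand" else e.pair.receptor_subunits
        for gene in subunits:
            acc[(cell, gene)] = acc.get((cell, gene), 0.0) + abs(e.weight)
    rows = sorted(acc.items(), key=lambda kv: (-kv[1], kv[0][1], kv[0][0]))
    return pd.DataFrame(
        [(ct, g, s) for (ct, g), s in rows], columns=["cell_type", "gene", "score"]
    )
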