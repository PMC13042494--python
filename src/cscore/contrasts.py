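"""Differential-expression contrast tables and their pairwise alignment.

A *contrast* is one case-vs-control comparison for one cell type, reduced
to per-feature effect sizes (log2 fold changes, or normalized enrichment
scores in pathway mode) and BH-adjusted FDRs.  Two contrasts over the same
cell type are inner-joined on feature id into a :class:`DualContrast`,
the input of the concordance (C-score) analysis.

Fitting the differential-expression model itself is out of scope: these
tables are the consumed product of an upstream DE (or GSEA) run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default column names of a contrast TSV; remappable via ``column_map``
DEFAULT_COLUMNS = {"feature": "feature", "effect": "log2fc", "fdr": "fdr"}


class EffectEntry(NamedTuple):
    """One feature's effect size and FDR in a single contrast."""

    feature_id: str
    effect: float
    fdr: float


class ContrastError(ValueError):
    """A contrast table violates its invariants."""


@dataclass(frozen=True)
class ContrastTable:
    """Per-feature effects and FDRs for one contrast in one cell type.

    Parameters
    ----------
    cell_type
        Cell-type label (e.g. ``"STB"``).
    contrast_label
        Name of the comparison (e.g. ``"O-A_vs_Control"``).
    data
        DataFrame with columns ``feature`` (str), ``effect`` (float) and
        ``fdr`` (float in [0, 1]); feature ids unique, table non-empty.
    """

    cell_type: str
    contrast_label: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = {"feature", "effect", "fdr"} - set(df.columns)
        if missing:
            raise ContrastError(f"contrast table missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise ContrastError("contrast table is empty")
        dup = df["feature"][df["feature"].duplicated()]
        if len(dup):
            raise ContrastError(
                f"duplicate feature id(s) in contrast table: {sorted(set(dup))[:5]}"
            )
        if df["feature"].astype(str).str.len().eq(0).any():
            raise ContrastError("empty feature id")
        eff = df["effect"].to_numpy(float)
        fdr = df["fdr"].to_numpy(float)
        if not np.isfinite(eff).all():
            raise ContrastError("non-finite effect values")
        if not np.isfinite(fdr).all() or (fdr < 0).any() or (fdr > 1).any():
            bad = df["feature"][(~np.isfinite(fdr)) | (fdr < 0) | (fdr > 1)]
            raise ContrastError(f"fdr outside [0, 1] for: {list(bad[:5])}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def feature_ids(self) -> pd.Series:
        return self.data["feature"]

    @property
    def entries(self) -> list[EffectEntry]:
        return [
            EffectEntry(str(f), float(e), float(q))
            for f, e, q in self.data[["feature", "effect", "fdr"]].itertuples(index=False)
        ]

    @classmethod
    def from_entries(
        cls, cell_type: str, contrast_label: str, entries: Sequence[EffectEntry]
    ) -> "ContrastTable":
        df = pd.DataFrame(entries, columns=["feature", "effect", "fdr"])
        return cls(cell_type, contrast_label, df)


def read_contrast_table(
    path: str | Path,
    cell_type: str = "",
    contrast_label: str = "",
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> ContrastTable:
    """Read a delimited contrast table (tab default, comma accepted).

    ``column_map`` maps the logical names ``feature``/``effect``/``fdr`` to
    the file's header names (default ``feature``/``log2fc``/``fdr``; a
    ``nes`` effect column can be mapped here for pathway mode).  Rows whose
    effect or fdr is missing or non-finite are dropped, with their 1-based
    data row numbers reported in the log.  A missing mapped column raises a
    :class:`ContrastError`; invariant violations (duplicate ids, fdr outside
    [0, 1]) propagate from :class:`ContrastTable`.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if sep is None:
        # tab-separated default; fall back to comma when the header has no tab
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={cols["feature"]: str})
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ContrastError(
            f"{path.name}: required column(s) {missing} not in header {list(df.columns)}"
        )
    df = df.rename(columns={v: k for k, v in cols.items()})[["feature", "effect", "fdr"]]
    numeric = df[["effect", "fdr"]].apply(pd.to_numeric, errors="coerce")
    ok = np.isfinite(numeric["effect"]) & np.isfinite(numeric["fdr"])
    if not ok.all():
        rows = [int(i) + 1 for i in np.flatnonzero(~ok.to_numpy())]
        logger.warning(
            "%s: dropped %d row(s) with missing/non-finite effect or fdr (rows %s)",
            path.name, len(rows), rows,
        )
    df = df[ok.to_numpy()].assign(effect=numeric["effect"][ok], fdr=numeric["fdr"][ok])
    return ContrastTable(
        cell_type or path.stem, contrast_label or path.stem, df.reset_index(drop=True)
    )


def write_contrast_table(
    table: ContrastTable, path: str | Path, column_map: Mapping[str, str] | None = None
) -> None:
    """Write a contrast table as TSV, full float precision (round-trip safe)."""
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    out = table.data.rename(columns=cols)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass(frozen=True)
class DualContrast:
    """Two contrasts inner-joined on feature id for one cell type.

    Houses the aligned arrays E1/FDR1 (contrast 1) and E2/FDR2 (contrast 2)
    over the lexicographically ordered intersection of feature ids.
    """

    cell_type: str
    features: np.ndarray
    e1: np.ndarray
    fdr1: np.ndarray
    e2: np.ndarray
    fdr2: np.ndarray
    contrast_labels: tuple[str, str] = ("contrast1", "contrast2")

    def __post_init__(self) -> None:
        n = len(self.features)
        if n == 0:
            raise ContrastError("empty feature set in DualContrast")
        for name in ("e1", "fdr1", "e2", "fdr2"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ContrastError(f"length mismatch: {name} has {len(arr)}, expected {n}")
        if len(set(self.features)) != n:
            raise ContrastError("duplicate feature ids in DualContrast")
        for name in ("fdr1", "fdr2"):
            arr = np.asarray(getattr(self, name), float)
            if (arr < 0).any() or (arr > 1).any():
                raise ContrastError(f"{name} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "e1": self.e1,
                "fdr1": self.fdr1,
                "e2": self.e2,
                "fdr2": self.fdr2,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cell_type: str = "") -> "DualContrast":
        df = df.sort_values("feature", kind="stable")
        return cls(
            cell_type=cell_type,
            features=df["feature"].to_numpy(str),
            e1=df["e1"].to_numpy(float),
            fdr1=df["fdr1"].to_numpy(float),
            e2=df["e2"].to_numpy(float),
            fdr2=df["fdr2"].to_numpy(float),
        )


def align_contrasts(
    a: ContrastTable, b: ContrastTable, missing_as_zero: bool = False
) -> DualContrast:
    """Inner-join two contrast tables on feature id into a :class:`DualContrast`.

    Features are ordered lexicographically so downstream results are
    independent of input row order.  Genes present in only one table are
    excluded (counts logged); with ``missing_as_zero`` they are instead kept
    with effect 0 and fdr 1, which the zero rule scores as 0.  A cell-type
    mismatch warns but does not fail; the first table's label is kept.
    """
    if a.cell_type != b.cell_type:
        logger.warning(
            "aligning contrasts with different cell types: %r vs %r",
            a.cell_type, b.cell_type,
        )
    ida = set(a.feature_ids)
    idb = set(b.feature_ids)
    keep = sorted(ida | idb) if missing_as_zero else sorted(ida & idb)
    if not keep:
        raise ContrastError(
            f"no common features between {a.contrast_label!r} and {b.contrast_label!r}"
        )
    dropped_a, dropped_b = len(ida - set(keep)), len(idb - set(keep))
    if dropped_a or dropped_b:
        logger.info(
            "align_contrasts: dropped %d feature(s) only in %r and %d only in %r",
            dropped_b if missing_as_zero else len(ida - idb), a.contrast_label,
            dropped_a if missing_as_zero else len(idb - ida), b.contrast_label,
        )
    sa = a.data.set_index("feature").reindex(keep)
    sb = b.data.set_index("feature").reindex(keep)
    return DualContrast(
        cell_type=a.cell_type,
        features=np.asarray(keep, dtype=str),
        e1=sa["effect"].fillna(0.0).to_numpy(float),
        fdr1=sa["fdr"].fillna(1.0).to_numpy(float),
        e2=sb["effect"].fillna(0.0).to_numpy(float),
        fdr2=sb["fdr"].fillna(1.0).to_numpy(float),
        contrast_labels=(a.contrast_label, b.contrast_label),
    )
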