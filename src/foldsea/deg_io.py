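"""Reading differential-expression tables and splitting DEGs by direction.

A differential-expression (DE) table pairs gene identifiers with signed
log2 fold changes and, optionally, adjusted p-values.  Enrichment by
fold-change interval operates on one regulation direction at a time, on
the *absolute* log fold changes: up- and down-regulated genes are split
into two lists, each sorted ascending by |logFC|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["DegTable", "RegulationList", "read_deg_table", "select_and_split"]


@dataclass
class DegTable:
    """Differential-expression records: one row per gene.

    Attributes
    ----------
    gene_id : list of str
        Unique gene identifiers (opaque, case-sensitive strings).
    log_fc : numpy.ndarray
        Signed log2 fold changes, finite.
    adj_p : numpy.ndarray or None
        Adjusted p-values in [0, 1], or None when the input had none.
    """

    gene_id: list[str]
    log_fc: np.ndarray
    adj_p: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.log_fc = np.asarray(self.log_fc, dtype=float)
        if self.adj_p is not None:
            self.adj_p = np.asarray(self.adj_p, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.gene_id) != len(self.log_fc):
            raise ValueError("gene_id and log_fc lengths differ")
        seen: set[str] = set()
        for g in self.gene_id:
            if g in seen:
                raise ValueError(f"duplicate gene_id: {g!r}")
            seen.add(g)
        if not np.all(np.isfinite(self.log_fc)):
            raise ValueError("log_fc contains non-finite values")
        if self.adj_p is not None:
            if len(self.adj_p) != len(self.gene_id):
                raise ValueError("adj_p length mismatch")
            ok = np.isnan(self.adj_p) | ((self.adj_p >= 0) & (self.adj_p <= 1))
            if not np.all(ok):
                raise ValueError("adj_p values outside [0, 1]")

    @property
    def n(self) -> int:
        return len(self.gene_id)

    def to_frame(self) -> pd.DataFrame:
        d = {"gene_id": self.gene_id, "log_fc": self.log_fc}
        if self.adj_p is not None:
            d["adj_p"] = self.adj_p
        return pd.DataFrame(d)


@dataclass
class RegulationList:
    """One direction's DEGs with their |logFC| values, sorted ascending.

    ``genes[i]`` carries the value ``abs_log_fc[i]``; ties in value are
    ordered lexicographically by gene id so the ranking is deterministic.
    The values only matter through their ranks, so any monotone transform
    of the fold changes yields the same downstream results.
    """

    direction: str
    genes: list[str]
    abs_log_fc: np.ndarray
    check_nonnegative: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.abs_log_fc = np.asarray(self.abs_log_fc, dtype=float)
        if len(self.genes) != len(self.abs_log_fc):
            raise ValueError("genes and abs_log_fc lengths differ")
        if np.any(np.diff(self.abs_log_fc) < 0):
            raise ValueError("abs_log_fc must be nondecreasing")
        if self.check_nonnegative and np.any(self.abs_log_fc < 0):
            raise ValueError("abs_log_fc must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def read_deg_table(
    path: str,
    gene_col: str = "gene_id",
    lfc_col: str = "log_fc",
    padj_col: str | None = None,
    delimiter: str = "\t",
) -> DegTable:
    """Read a delimited DE table with a header line.

    Rows whose fold change is missing or non-numeric are dropped (the
    count is logged).  Duplicate gene identifiers are an error.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={0: str})
    for col in [gene_col, lfc_col] + ([padj_col] if padj_col else []):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    lfc = pd.to_numeric(df[lfc_col], errors="coerce")
    keep = lfc.notna() & np.isfinite(lfc)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing/non-numeric fold change", n_dropped)
    df = df.loc[keep]
    genes = df[gene_col].astype(str).tolist()
    dups = pd.Series(genes)[pd.Series(genes).duplicated()]
    if not dups.empty:
        raise ValueError(f"duplicate gene_id: {dups.iloc[0]!r}")
    adj_p = None
    if padj_col is not None:
        adj_p = pd.to_numeric(df[padj_col], errors="coerce").to_numpy()
    return DegTable(genes, lfc.loc[keep].to_numpy(), adj_p)


def select_and_split(
    table: DegTable,
    min_abs_lfc: float = 0.0,
    max_padj: float | None = None,
) -> tuple[RegulationList, RegulationList]:
    """Select DEGs and split them into up- and down-regulated lists.

    A row is retained when ``|log_fc| >= min_abs_lfc`` and, if a
    significance column exists and ``max_padj`` is given,
    ``adj_p <= max_padj``.  Genes with ``log_fc`` exactly 0 are neither
    up- nor down-regulated and are excluded.  Each output list is sorted
    ascending by |logFC| with lexicographic gene-id tie-breaks, so the
    result does not depend on input row order.
    """
    if table.n == 0:
        raise ValueError("DEG table is empty")
    if min_abs_lfc < 0:
        raise ValueError("min_abs_lfc must be >= 0")

    abs_lfc = np.abs(table.log_fc)
    keep = abs_lfc >= min_abs_lfc
    if max_padj is not None and table.adj_p is not None:
        keep &= ~np.isnan(table.adj_p) & (table.adj_p <= max_padj)

    out: dict[str, list[tuple[float, str]]] = {"up": [], "down": []}
    for i in np.flatnonzero(keep):
        lfc = table.log_fc[i]
        if lfc > 0:
            out["up"].append((abs_lfc[i], table.gene_id[i]))
        elif lfc < 0:
            out["down"].append((abs_lfc[i], table.gene_id[i]))
        # lfc == 0: neither direction

    lists = {}
    for direction, pairs in out.items():
        pairs.sort(key=lambda t: (t[0], t[1]))
        lists[direction] = RegulationList(
            direction=direction,
            genes=[g for _, g in pairs],
            abs_log_fc=np.array([v for v, _ in pairs], dtype=float),
        )
    if lists["up"].n == 0 and lists["down"].n == 0:
        raise ValueError("no DEGs after filtering")
    return lists["up"], lists["down"]
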