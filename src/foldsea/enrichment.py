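"""Fold-change-specific enrichment analysis (FSEA) and a SEA baseline.

FSEA asks a sharper question than classic overrepresentation analysis:
not merely *whether* a functional gene group is enriched among
differentially expressed genes, but whether its members concentrate in
a specific *fold-change interval*.  The |logFC|-sorted DEG list of one
regulation direction is cut into ``k`` quantiles; every contiguous
union of neighboring quantiles except the full range is a candidate
interval.  For each annotation term and each interval a one-sided
Fisher exact test compares the term's membership inside versus outside
the interval, the interval with the minimal raw p is reported per term,
and the multiple-testing correction is applied jointly over all
``s * (k(k+1)/2 - 1)`` tests (``s`` terms times the number of
intervals).  A term whose best interval survives the correction is
*fold-change-specific*: its genes respond coordinately with a
particular strength (for ``k = 5``, intervals 1..5 read as very weak to
very strong response).

The SEA baseline is the ordinary one-sided Fisher test of term
membership against DEG status over a gene universe, BH-corrected across
terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .annotation_io import AnnotationMap, restrict_annotation
from .deg_io import RegulationList

__all__ = [
    "QuantilePartition",
    "FoldChangeInterval",
    "ContingencyTable",
    "FseaRecord",
    "FseaResult",
    "SeaRecord",
    "SeaResult",
    "build_quantile_partition",
    "enumerate_intervals",
    "n_intervals",
    "contingency_table",
    "fisher_greater",
    "adjust_pvalues",
    "run_fsea",
    "run_sea",
    "compare_fsea_sea",
]


@dataclass(frozen=True)
class FoldChangeInterval:
    """Contiguous union of quantiles [lo, hi], 1-based, never the full range."""

    lo: int
    hi: int

    @property
    def width(self) -> int:
        return self.hi - self.lo + 1

    def __str__(self) -> str:
        return f"[{self.lo},{self.hi}]"


@dataclass
class QuantilePartition:
    """Assignment of a sorted regulation list to ``k`` quantiles.

    Genes are assigned by rank: the gene at ascending 1-based rank ``p``
    (ties broken lexicographically upstream) goes to quantile
    ``ceil(p * k / n)``, so quantile sizes differ by at most one and the
    maximum-value gene always lands in the last quantile.  Boundary
    values report the |logFC| of the last gene of quantiles 1..k-1.
    """

    k: int
    boundaries: np.ndarray
    assignment: dict[str, int]
    sizes: np.ndarray
    quantile_index: np.ndarray = field(repr=False)  # per rank, 0-based quantile

    def genes_in_interval(self, interval: FoldChangeInterval, genes: list[str]) -> set[str]:
        """Genes of the sorted list falling into ``interval``."""
        mask = (self.quantile_index >= interval.lo - 1) & (
            self.quantile_index <= interval.hi - 1
        )
        return {g for g, m in zip(genes, mask) if m}


@dataclass
class ContingencyTable:
    """2x2 table for one (term, interval) Fisher test.

    A = term genes inside the interval, B = term genes outside it (but
    in the DEG list), C = non-term genes inside, D = the rest;
    N = A+B+C+D is the size of the direction's DEG list.
    """

    A: int
    B: int
    C: int
    D: int

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C, self.D) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def N(self) -> int:
        return self.A + self.B + self.C + self.D


@dataclass
class FseaRecord:
    term_id: str
    direction: str
    best_interval: FoldChangeInterval
    table: ContingencyTable
    p_raw: float
    p_adj: float
    significant: bool
    term_name: str | None = None


@dataclass
class FseaResult:
    records: list[FseaRecord]
    k: int
    s: int
    fdr_threshold: float
    method: str
    direction: str

    @property
    def n_intervals(self) -> int:
        return n_intervals(self.k)

    @property
    def m(self) -> int:
        """Total number of tests entering the correction."""
        return self.s * self.n_intervals

    @property
    def significant_terms(self) -> set[str]:
        return {r.term_id for r in self.records if r.significant}


@dataclass
class SeaRecord:
    term_id: str
    deg_hits: int
    deg_total: int
    bg_hits: int
    bg_total: int
    p_raw: float
    p_adj: float
    significant: bool
    term_name: str | None = None


@dataclass
class SeaResult:
    records: list[SeaRecord]
    s: int
    fdr_threshold: float

    @property
    def significant_terms(self) -> set[str]:
        return {r.term_id for r in self.records if r.significant}


def build_quantile_partition(reg: RegulationList, k: int) -> QuantilePartition:
    """Split a sorted regulation list into ``k`` rank-based quantiles."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n = reg.n
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of genes n = {n}")
    ranks = np.arange(1, n + 1)
    qidx = np.ceil(ranks * k / n).astype(int) - 1  # 0-based
    sizes = np.bincount(qidx, minlength=k)
    # boundary i (1-based quantile) = |logFC| of the last gene of that quantile
    last_rank = np.flatnonzero(np.diff(qidx, append=k))  # last index of each quantile
    boundaries = reg.abs_log_fc[last_rank[:-1]]
    assignment = {g: int(q) + 1 for g, q in zip(reg.genes, qidx)}
    return QuantilePartition(
        k=k,
        boundaries=np.asarray(boundaries, dtype=float),
        assignment=assignment,
        sizes=sizes,
        quantile_index=qidx,
    )


def n_intervals(k: int) -> int:
    """Number of tested fold-change intervals for ``k`` quantiles."""
    if k < 2:
        raise ValueError("k must be >= 2")
    return k * (k + 1) // 2 - 1


def enumerate_intervals(k: int) -> list[FoldChangeInterval]:
    """All contiguous quantile unions [lo, hi] except the full range [1, k].

    Ordered by ``lo`` then ``hi``; the count is ``k(k+1)/2 - 1`` (for
    ``k = 5``: 14 intervals).  The full range is excluded because it is
    the comparison background itself.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    return [
        FoldChangeInterval(lo, hi)
        for lo in range(1, k + 1)
        for hi in range(lo, k + 1)
        if not (lo == 1 and hi == k)
    ]


def contingency_table(
    term_genes: set[str], interval_genes: set[str], deg_genes: set[str]
) -> ContingencyTable:
    """Build the 2x2 table of term membership versus interval membership."""
    if not interval_genes <= deg_genes:
        raise ValueError("interval_genes must be a subset of deg_genes")
    term_in_deg = set(term_genes) & deg_genes
    a = len(term_in_deg & interval_genes)
    b = len(term_in_deg) - a
    c = len(interval_genes) - a
    d = len(deg_genes) - len(term_in_deg) - c
    return ContingencyTable(a, b, c, d)


def fisher_greater(table: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher exact p-value for a 2x2 table.

    Equals the hypergeometric upper tail P(X >= A) with population N,
    A+B successes and A+C draws.  An empty margin (or empty table) gives
    p = 1.
    """
    if table.N == 0:
        return 1.0
    p = float(hypergeom.sf(table.A - 1, table.N, table.A + table.B, table.A + table.C))
    return min(max(p, 0.0), 1.0)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (flat array)."""
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def adjust_pvalues(
    p_matrix: np.ndarray, method: str = "bh", total_tests: int | None = None
) -> np.ndarray:
    """Adjust raw p-values jointly over all entries.

    ``total_tests`` must equal the number of entries; it exists so the
    caller states the intended correction budget explicitly (for FSEA:
    ``s`` terms times the interval count).
    """
    p = np.asarray(p_matrix, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if total_tests is not None and total_tests != m:
        raise ValueError(f"total_tests = {total_tests} does not match {m} p-values")
    if method == "bh":
        return _bh_adjust(p.ravel()).reshape(p.shape)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    raise ValueError(f"unknown correction method: {method!r}")


def _interval_pvalues(
    reg: RegulationList,
    annotation: AnnotationMap,
    k: int,
) -> tuple[list[str], np.ndarray, np.ndarray, list[FoldChangeInterval], QuantilePartition]:
    """Raw Fisher p for every (term, interval) pair, vectorized.

    Returns (term ids, p matrix s x n_intervals, A matrix, intervals,
    partition).  Per-term quantile counts are accumulated once; interval
    counts are differences of the cumulative counts, and the whole p
    matrix is one broadcast hypergeometric survival-function call.
    """
    part = build_quantile_partition(reg, k)
    n = reg.n
    gene_rank = {g: i for i, g in enumerate(reg.genes)}
    terms = sorted(annotation.term_to_genes)
    s = len(terms)

    counts = np.zeros((s, k), dtype=np.int64)
    for ti, term in enumerate(terms):
        idx = [gene_rank[g] for g in annotation.term_to_genes[term] if g in gene_rank]
        if idx:
            counts[ti] = np.bincount(part.quantile_index[idx], minlength=k)

    intervals = enumerate_intervals(k)
    lo = np.array([iv.lo for iv in intervals]) - 1
    hi = np.array([iv.hi for iv in intervals])

    csum = np.concatenate([np.zeros((s, 1), dtype=np.int64), np.cumsum(counts, axis=1)], axis=1)
    A = csum[:, hi] - csum[:, lo]  # s x n_int
    size_csum = np.concatenate([[0], np.cumsum(part.sizes)])
    draws = size_csum[hi] - size_csum[lo]  # interval sizes

    t = counts.sum(axis=1)  # term size within this direction
    p = hypergeom.sf(A - 1, n, t[:, None], draws[None, :])
    p = np.clip(p, 0.0, 1.0)
    return terms, p, A, intervals, part


def _best_interval_index(
    p_row: np.ndarray, intervals: list[FoldChangeInterval]
) -> int:
    """Index of the minimal-p interval; ties go to the widest, then smallest lo."""
    keys = [
        (p_row[j], -(iv.hi - iv.lo), iv.lo) for j, iv in enumerate(intervals)
    ]
    return min(range(len(intervals)), key=keys.__getitem__)


def run_fsea(
    reg: RegulationList,
    annotation: AnnotationMap,
    k: int = 5,
    fdr: float = 0.05,
    method: str = "bh",
) -> FseaResult:
    """Run FSEA on one regulation direction.

    The annotation is restricted to the genes of ``reg`` (terms left
    with no gene are dropped, and ``s`` counts the remaining terms).
    Every term x interval raw p is corrected jointly; per term the
    minimal-p interval is reported, and the term is fold-change-specific
    when the adjusted p of that interval is at most ``fdr``.
    """
    if not 0 < fdr <= 1:
        raise ValueError("fdr must be in (0, 1]")
    restricted = restrict_annotation(
        annotation, reg.gene_set, min_term_size=1
    ) if annotation.s else annotation
    if restricted.s == 0:
        raise ValueError("no testable terms")

    terms, p, A, intervals, part = _interval_pvalues(reg, restricted, k)
    p_adj = adjust_pvalues(p, method=method, total_tests=p.size)

    deg_genes = reg.gene_set
    records = []
    for ti, term in enumerate(terms):
        j = _best_interval_index(p[ti], intervals)
        iv = intervals[j]
        interval_genes = part.genes_in_interval(iv, reg.genes)
        table = contingency_table(restricted.term_to_genes[term], interval_genes, deg_genes)
        adj = float(p_adj[ti, j])
        records.append(
            FseaRecord(
                term_id=term,
                term_name=restricted.term_names.get(term),
                direction=reg.direction,
                best_interval=iv,
                table=table,
                p_raw=float(p[ti, j]),
                p_adj=adj,
                significant=bool(adj <= fdr),
            )
        )
    records.sort(key=lambda r: (r.p_adj, r.p_raw, r.term_id))
    return FseaResult(
        records=records,
        k=k,
        s=len(terms),
        fdr_threshold=fdr,
        method=method,
        direction=reg.direction,
    )


def run_sea(
    deg_genes: set[str],
    universe: set[str],
    annotation: AnnotationMap,
    fdr: float = 0.05,
) -> SeaResult:
    """Classic singular enrichment analysis: DEGs versus the universe.

    Per term, a one-sided Fisher test of term membership against DEG
    status over ``universe``; BH correction across the ``s`` terms.
    """
    deg_genes = set(deg_genes)
    universe = set(universe)
    if not deg_genes <= universe:
        raise ValueError("deg_genes must be a subset of universe")
    restricted = restrict_annotation(annotation, universe, min_term_size=1)
    if restricted.s == 0:
        raise ValueError("no testable terms")
    terms = sorted(restricted.term_to_genes)
    n_universe = len(universe)
    n_deg = len(deg_genes)

    bg_hits = np.array([len(restricted.term_to_genes[t]) for t in terms])
    deg_hits = np.array(
        [len(restricted.term_to_genes[t] & deg_genes) for t in terms]
    )
    p = np.clip(hypergeom.sf(deg_hits - 1, n_universe, bg_hits, n_deg), 0.0, 1.0)
    p_adj = adjust_pvalues(p, method="bh", total_tests=p.size)

    records = [
        SeaRecord(
            term_id=t,
            term_name=restricted.term_names.get(t),
            deg_hits=int(deg_hits[i]),
            deg_total=n_deg,
            bg_hits=int(bg_hits[i]),
            bg_total=n_universe,
            p_raw=float(p[i]),
            p_adj=float(p_adj[i]),
            significant=bool(p_adj[i] <= fdr),
        )
        for i, t in enumerate(terms)
    ]
    records.sort(key=lambda r: (r.p_adj, r.p_raw, r.term_id))
    return SeaResult(records=records, s=len(terms), fdr_threshold=fdr)


def compare_fsea_sea(fsea: FseaResult, sea: SeaResult) -> dict:
    """Partition significant terms into both / FSEA-only / SEA-only."""
    f = fsea.significant_terms
    s = sea.significant_terms
    return {
        "both": sorted(f & s),
        "fsea_only": sorted(f - s),
        "sea_only": sorted(s - f),
        "n_both": len(f & s),
        "n_fsea_only": len(f - s),
        "n_sea_only": len(s - f),
    }
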