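"""Gene-to-term annotation handling.

Supports three input dialects (plain two-column TSV, GAF 2.x, NCBI
gene2go), optional true-path propagation over an OBO ontology
(``is_a`` / ``part_of`` closure), and restriction of an annotation to a
gene universe with term-size filtering.

Propagation is off by default: annotation maps exported from pre-built
resources (e.g. ``org.*.eg.db`` packages) usually already contain
ancestor terms, and propagating them again is harmless only when the
caller knows that is the case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMap",
    "OntologyGraph",
    "read_annotation",
    "read_obo",
    "propagate_annotations",
    "restrict_annotation",
    "write_annotation",
]

_ASPECTS = {"P", "F", "C"}
_GENE2GO_CATEGORY = {"Process": "P", "Function": "F", "Component": "C"}


@dataclass
class AnnotationMap:
    """Bidirectional gene <-> term mapping.

    ``term_to_genes`` and ``gene_to_terms`` are kept as exact inverses;
    terms with no genes are never stored.  ``s`` is the number of terms,
    which is also the term count entering the multiple-testing budget of
    the enrichment procedures.
    """

    term_to_genes: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.term_to_genes = {
            t: set(gs) for t, gs in self.term_to_genes.items() if gs
        }
        self._rebuild_inverse()

    def _rebuild_inverse(self) -> None:
        inv: dict[str, set[str]] = {}
        for term, genes in self.term_to_genes.items():
            for g in genes:
                inv.setdefault(g, set()).add(term)
        self.gene_to_terms: dict[str, set[str]] = inv

    @property
    def s(self) -> int:
        return len(self.term_to_genes)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_terms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationMap):
            return NotImplemented
        return self.term_to_genes == other.term_to_genes


@dataclass
class OntologyGraph:
    """Directed acyclic graph of ontology terms, edges child -> parent.

    Only ``is_a`` and ``part_of`` relations are retained; both are
    transitive for annotation purposes (the true-path rule).
    """

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph contains a cycle")

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str]] | list[tuple[str, str, str]],
        nodes: list[str] | None = None,
    ) -> "OntologyGraph":
        g = nx.DiGraph()
        if nodes:
            g.add_nodes_from(nodes)
        for e in edges:
            child, parent = e[0], e[1]
            rel = e[2] if len(e) > 2 else "is_a"
            g.add_edge(child, parent, relation=rel)
        return cls(g)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` along child->parent edges."""
        return set(nx.descendants(self.graph, term))

    def __contains__(self, term: str) -> bool:
        return term in self.graph


def read_obo(path: str) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file, keeping is_a / part_of edges.

    Obsolete terms are skipped.  Raises on a cyclic graph.
    """
    import obonet

    multigraph = obonet.read_obo(path, ignore_obsolete=True)
    g = nx.DiGraph()
    g.add_nodes_from(multigraph.nodes)
    for child, parent, rel in multigraph.edges(keys=True):
        if rel in ("is_a", "part_of"):
            g.add_edge(child, parent, relation=rel)
    return OntologyGraph(g)


def _parse_tsv2col(path: str) -> tuple[dict[str, set[str]], dict[str, str]]:
    term_to_genes: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected gene<TAB>term")
            gene, term = parts[0], parts[1]
            term_to_genes.setdefault(term, set()).add(gene)
    return term_to_genes, {}


def _parse_gaf(
    path: str,
    aspect_filter: set[str] | None,
    taxon_filter: str | None,
    exclude_evidence: set[str] | None,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    term_to_genes: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                raise ValueError(f"{path}:{lineno}: GAF row has {len(cols)} columns, expected >= 15")
            gene, qualifier, term = cols[1], cols[3], cols[4]
            evidence, aspect, symbol = cols[6], cols[8], cols[2]
            taxon = cols[12]
            if "NOT" in qualifier.split("|"):
                continue
            if aspect_filter is not None and aspect not in aspect_filter:
                continue
            if taxon_filter is not None:
                taxa = {t.split(":")[-1] for t in taxon.split("|")}
                if str(taxon_filter) not in taxa:
                    continue
            if exclude_evidence is not None and evidence in exclude_evidence:
                continue
            term_to_genes.setdefault(term, set()).add(gene)
    return term_to_genes, names


def _parse_gene2go(
    path: str,
    aspect_filter: set[str] | None,
    taxon_filter: str | None,
    exclude_evidence: set[str] | None,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    term_to_genes: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise ValueError(f"{path}:{lineno}: gene2go row has {len(cols)} columns, expected 8")
            tax_id, gene, term, evidence, qualifier, term_name, _pubmed, category = cols[:8]
            if "NOT" in qualifier.split("|") or qualifier == "NOT":
                continue
            if taxon_filter is not None and tax_id != str(taxon_filter):
                continue
            aspect = _GENE2GO_CATEGORY.get(category)
            if aspect_filter is not None and aspect not in aspect_filter:
                continue
            if exclude_evidence is not None and evidence in exclude_evidence:
                continue
            term_to_genes.setdefault(term, set()).add(gene)
            if term_name and term_name != "-":
                names[term] = term_name
    return term_to_genes, names


def read_annotation(
    path: str,
    format: str = "tsv2col",
    aspect_filter: set[str] | None = None,
    taxon_filter: str | None = None,
    exclude_evidence: set[str] | None = None,
) -> AnnotationMap:
    """Read a gene->term annotation file into an :class:`AnnotationMap`.

    Parameters
    ----------
    format : {"tsv2col", "gaf", "gene2go"}
        File dialect.  ``tsv2col`` is gene<TAB>term per line; GAF rows
        whose qualifier contains ``NOT`` are dropped; gene2go uses the
        NCBI column layout with GeneID as the gene identifier.
    aspect_filter : subset of {"P", "F", "C"}, optional
        Keep only these ontology aspects (GAF / gene2go only).
    taxon_filter : str or int, optional
        Keep only rows for this NCBI taxon id (GAF / gene2go only).
    exclude_evidence : set of str, optional
        Evidence codes to drop, e.g. ``{"IEA"}``.
    """
    if aspect_filter is not None:
        aspect_filter = set(aspect_filter)
        if not aspect_filter <= _ASPECTS:
            raise ValueError(f"aspect_filter must be a subset of {_ASPECTS}")
    if format == "tsv2col":
        term_to_genes, names = _parse_tsv2col(path)
    elif format == "gaf":
        term_to_genes, names = _parse_gaf(path, aspect_filter, taxon_filter, exclude_evidence)
    elif format == "gene2go":
        term_to_genes, names = _parse_gene2go(path, aspect_filter, taxon_filter, exclude_evidence)
    else:
        raise ValueError(f"unknown annotation format: {format!r}")
    if not term_to_genes:
        raise ValueError("no annotations retained")
    return AnnotationMap(term_to_genes, term_names=names)


def write_annotation(annotation: AnnotationMap, path: str) -> None:
    """Write an annotation as a two-column gene<TAB>term TSV (sorted)."""
    with open(path, "w") as fh:
        for term in sorted(annotation.term_to_genes):
            for gene in sorted(annotation.term_to_genes[term]):
                fh.write(f"{gene}\t{term}\n")


def propagate_annotations(
    annotation: AnnotationMap, ontology: OntologyGraph
) -> AnnotationMap:
    """Apply the true-path rule: annotate each gene to all ancestors.

    A gene annotated to a term becomes annotated to every ancestor of
    that term along ``is_a`` / ``part_of`` edges.  Annotated terms
    absent from the ontology pass through unchanged (with a warning).
    The operation is idempotent.
    """
    out: dict[str, set[str]] = {t: set(g) for t, g in annotation.term_to_genes.items()}
    missing = []
    for term, genes in annotation.term_to_genes.items():
        if term not in ontology:
            missing.append(term)
            continue
        for anc in ontology.ancestors(term):
            out.setdefault(anc, set()).update(genes)
    if missing:
        logger.warning(
            "%d annotated terms not in ontology; passed through unchanged", len(missing)
        )
    return AnnotationMap(out, term_names=dict(annotation.term_names))


def restrict_annotation(
    annotation: AnnotationMap,
    universe: set[str],
    min_term_size: int = 2,
    max_term_size: int | None = None,
) -> AnnotationMap:
    """Restrict an annotation to a gene universe and filter by term size.

    Genes outside ``universe`` are removed; terms whose remaining gene
    count falls outside ``[min_term_size, max_term_size]`` are dropped.
    The default minimum of 2 discards single-gene terms, which cannot
    support a meaningful interval enrichment and only inflate the term
    count entering the multiple-testing correction.
    """
    if not universe:
        raise ValueError("universe is empty")
    if min_term_size < 1:
        raise ValueError("min_term_size must be >= 1")
    if max_term_size is not None and max_term_size < min_term_size:
        raise ValueError("max_term_size must be >= min_term_size")
    out: dict[str, set[str]] = {}
    for term, genes in annotation.term_to_genes.items():
        kept = genes & universe
        if len(kept) < min_term_size:
            continue
        if max_term_size is not None and len(kept) > max_term_size:
            continue
        out[term] = kept
    return AnnotationMap(out, term_names=dict(annotation.term_names))
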