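"""Gene Ontology structure, annotations, propagation and category tables.

The GO graph is read from an OBO 1.2 file; only ``is_a`` edges define the
hierarchy used for annotation propagation (``part_of`` traversal can be
enabled explicitly but is off by default).  Annotations are read from GAF 2.x
files with NOT-qualified and ND-evidence rows excluded, and each gene's direct
annotations are propagated to all transitive ``is_a`` ancestors before
category gene sets are formed.  Category sizes are always computed after
intersecting with the measured-gene universe, because enrichment scores exist
only for measured genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OboParseError",
    "GafParseError",
    "OntologyGraph",
    "AnnotationSet",
    "Category",
    "CategoryTable",
    "parse_obo",
    "parse_gaf",
    "propagate_annotations",
    "build_category_table",
    "load_mapping",
]

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class OboParseError(ValueError):
    pass


class GafParseError(ValueError):
    pass


@dataclass
class OntologyGraph:
    """GO term hierarchy: nodes are terms, directed edges point child -> parent.

    ``graph`` holds one edge per (child, parent, relation); obsolete terms are
    retained as nodes but flagged and never traversed.
    """

    graph: nx.MultiDiGraph

    def __post_init__(self) -> None:
        isa = self.isa_subgraph()
        if not nx.is_directed_acyclic_graph(isa):
            cycle = nx.find_cycle(isa)
            raise OboParseError(f"is_a hierarchy contains a cycle: {cycle}")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def is_obsolete(self, term_id: str) -> bool:
        return str(self.graph.nodes[term_id].get("is_obsolete", "")).lower() == "true"

    def name(self, term_id: str) -> str:
        return self.graph.nodes[term_id].get("name", term_id)

    def namespace(self, term_id: str) -> str | None:
        return self.graph.nodes[term_id].get("namespace")

    def isa_subgraph(self, include_part_of: bool = False) -> nx.DiGraph:
        """Directed child->parent graph restricted to is_a (and optionally
        part_of) edges between non-obsolete terms."""
        relations = {"is_a"} | ({"part_of"} if include_part_of else set())
        g = nx.DiGraph()
        for n, data in self.graph.nodes(data=True):
            if str(data.get("is_obsolete", "")).lower() != "true":
                g.add_node(n)
        for u, v, rel in self.graph.edges(keys=True):
            if rel in relations and g.has_node(u) and g.has_node(v):
                g.add_edge(u, v)
        return g

    def ancestors(self, term_id: str, include_part_of: bool = False) -> set[str]:
        g = self.isa_subgraph(include_part_of)
        if term_id not in g:
            return set()
        return nx.descendants(g, term_id)  # edges point child -> parent


@dataclass
class AnnotationSet:
    """Gene -> GO term annotation records (post NOT/ND exclusion)."""

    records: pd.DataFrame  # columns gene_id, term_id, qualifier, evidence_code

    REQUIRED = ("gene_id", "term_id", "qualifier", "evidence_code")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"annotation records missing columns: {missing}")
        rec = self.records
        bad = rec["qualifier"].fillna("").str.contains("NOT") | (rec["evidence_code"] == "ND")
        if bad.any():
            raise ValueError("AnnotationSet must not contain NOT/ND records")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def term_ids(self) -> set[str]:
        return set(self.records["term_id"].unique())


def _find_bad_obo_line(path) -> int | None:
    """Best-effort line number of the first malformed tag line."""
    with open(path, encoding="utf-8") as fh:
        in_stanza = False
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("["):
                in_stanza = True
                continue
            if in_stanza and line and not line.startswith("!") and ":" not in line:
                return i
    return None


def parse_obo(path) -> OntologyGraph:
    """Read an OBO 1.2 ontology file into an :class:`OntologyGraph`.

    Obsolete terms are retained (flagged) but excluded from propagation.
    """
    try:
        g = obonet.read_obo(path, ignore_obsolete=False)
    except ValueError as exc:
        lineno = _find_bad_obo_line(path)
        at = f" at line {lineno}" if lineno is not None else ""
        raise OboParseError(f"malformed OBO stanza in {path}{at}: {exc}") from exc
    return OntologyGraph(graph=g)


GAF_COLUMNS = [
    "db", "gene_id", "db_object_symbol", "qualifier", "term_id", "db_reference",
    "evidence_code", "with_from", "aspect", "db_object_name", "db_object_synonym",
    "db_object_type", "taxon", "date", "assigned_by", "annotation_extension",
    "gene_product_form_id",
]


def parse_gaf(path) -> AnnotationSet:
    """Read a GAF 2.x annotation file, excluding NOT and ND annotations.

    Lines starting with ``!`` are comments.  GAF rows carry 15 (2.0) or 17
    (2.1/2.2) tab-separated columns; anything else is a parse error naming the
    offending row.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) not in (15, 17):
                raise GafParseError(
                    f"{path} row {i}: expected 15 or 17 tab-separated columns, got {len(parts)}"
                )
            parts += [""] * (17 - len(parts))
            rows.append(parts)
    df = pd.DataFrame(rows, columns=GAF_COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=GAF_COLUMNS)
    keep = ~(df["qualifier"].str.contains("NOT") | (df["evidence_code"] == "ND"))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("parse_gaf: excluded %d NOT/ND annotation rows", n_dropped)
    out = df.loc[keep, ["gene_id", "term_id", "qualifier", "evidence_code"]]
    return AnnotationSet(out.reset_index(drop=True))


def propagate_annotations(
    graph: OntologyGraph,
    annotations: AnnotationSet,
    include_part_of: bool = False,
) -> AnnotationSet:
    """Propagate each annotation to every transitive ``is_a`` ancestor.

    Output is deduplicated per (gene, term).  Annotations to terms absent
    from the graph (or obsolete) are dropped with a logged warning.
    """
    isa = graph.isa_subgraph(include_part_of)
    # precompute the ancestor closure once per annotated term
    closures: dict[str, set[str]] = {}
    pairs: set[tuple[str, str]] = set()
    dropped = 0
    for gene, term in annotations.records[["gene_id", "term_id"]].itertuples(index=False):
        if term not in isa:
            dropped += 1
            continue
        if term not in closures:
            closures[term] = {term} | nx.descendants(isa, term)
        for t in closures[term]:
            pairs.add((gene, t))
    if dropped:
        logger.warning("propagate_annotations: dropped %d annotations to unknown/obsolete terms", dropped)
    df = pd.DataFrame(sorted(pairs), columns=["gene_id", "term_id"])
    df["qualifier"] = ""
    df["evidence_code"] = ""
    return AnnotationSet(df)


def load_mapping(path) -> dict[str, str]:
    """Two-column id -> id mapping table (TSV with header)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError(f"mapping table must have 2 columns, got {df.shape[1]}")
    src = df.iloc[:, 0].astype(str)
    if src.duplicated().any():
        dupes = src[src.duplicated()].unique().tolist()
        raise ValueError(f"mapping table has duplicate source ids: {dupes[:5]}")
    return dict(zip(src, df.iloc[:, 1].astype(str)))


@dataclass(frozen=True)
class Category:
    category_id: str
    name: str
    genes: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class CategoryTable:
    """Ordered collection of gene categories with set-semantics membership."""

    categories: list[Category]

    def __post_init__(self) -> None:
        ids = [c.category_id for c in self.categories]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate category ids")
        self.categories = sorted(self.categories, key=lambda c: c.category_id)

    def __len__(self) -> int:
        return len(self.categories)

    def __iter__(self):
        return iter(self.categories)

    def __getitem__(self, category_id: str) -> Category:
        for c in self.categories:
            if c.category_id == category_id:
                return c
        raise KeyError(category_id)

    @property
    def category_ids(self) -> list[str]:
        return [c.category_id for c in self.categories]

    @property
    def sizes(self) -> pd.Series:
        return pd.Series({c.category_id: c.size for c in self.categories}, name="size")

    def names(self) -> pd.Series:
        return pd.Series({c.category_id: c.name for c in self.categories}, name="name")

    def membership_matrix(self, gene_ids) -> "scipy.sparse.csr_matrix":
        """Sparse category x gene indicator matrix over *gene_ids* order."""
        from scipy import sparse

        col = {g: j for j, g in enumerate(gene_ids)}
        rows, cols = [], []
        for i, c in enumerate(self.categories):
            for g in c.genes:
                j = col.get(g)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
        return sparse.csr_matrix(
            ([1.0] * len(rows), (rows, cols)), shape=(len(self.categories), len(col))
        )

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = [
            {"category_id": c.category_id, "name": c.name, "gene_ids": sorted(c.genes)}
            for c in self.categories
        ]
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "CategoryTable":
        payload = json.loads(Path(path).read_text())
        return cls([
            Category(e["category_id"], e["name"], frozenset(e["gene_ids"])) for e in payload
        ])

    def to_gmt(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for c in self.categories:
                fh.write("\t".join([c.category_id, c.name, *sorted(c.genes)]) + "\n")

    @classmethod
    def from_gmt(cls, path) -> "CategoryTable":
        cats = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    continue
                cats.append(Category(parts[0], parts[1], frozenset(parts[2:])))
        return cls(cats)


def build_category_table(
    annotations: AnnotationSet,
    universe,
    graph: OntologyGraph | None = None,
    namespace: str | None = "biological_process",
    size_min: int = 10,
    size_max: int = 200,
    mapping: dict[str, str] | None = None,
) -> CategoryTable:
    """Form size-filtered category gene sets from propagated annotations.

    Gene ids are first passed through the optional *mapping* (unmapped genes
    dropped, count logged), then intersected with the measured-gene
    *universe*; the size filter applies to the post-intersection size so that
    ``s`` matches the resampling pool of measured genes.  When *graph* is
    given, categories are restricted to *namespace* and labelled with term
    names; without a graph no namespace filter can be applied.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("measured-gene universe is empty")
    rec = annotations.records[["gene_id", "term_id"]].copy()
    if mapping is not None:
        mapped = rec["gene_id"].map(mapping)
        n_unmapped = int(mapped.isna().sum())
        if n_unmapped:
            logger.info("build_category_table: dropped %d annotations for unmapped genes", n_unmapped)
        rec = rec.assign(gene_id=mapped).dropna(subset=["gene_id"])
    rec = rec[rec["gene_id"].isin(universe)]
    cats: list[Category] = []
    for term, grp in rec.groupby("term_id", sort=True):
        if graph is not None:
            if term not in graph.terms or graph.is_obsolete(term):
                continue
            if namespace is not None and graph.namespace(term) != namespace:
                continue
        genes = frozenset(grp["gene_id"])
        if size_min <= len(genes) <= size_max:
            name = graph.name(term) if graph is not None else term
            cats.append(Category(term, name, genes))
    return CategoryTable(cats)
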