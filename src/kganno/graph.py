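"""Typed biological knowledge graph.

The graph holds three node types — cell types (from an ontology), genes and
pathways (from gene-set files) — connected by directed, typed relationships:

====================  =====================  ============================================
relation              endpoints              meaning
====================  =====================  ============================================
``IS_A``              CellType -> CellType   ontology hierarchy (child -> parent)
``PARTICIPATES_IN``   Gene -> Pathway        gene-set membership
``COEXPRESSED_IN``    Gene -> Gene           correlated expression within a cell type
``HAS_ACTIVITY_IN``   Pathway -> CellType    pathway activity elevated in a cell type
``IS_MARKER_FOR``     Gene -> CellType       curated marker association (optional)
====================  =====================  ============================================

The first two relations are loaded from reference files (OBO, GMT); the
expression-derived relations are inferred per dataset by
:mod:`kganno.construct`.  Storage is in-memory with per-relation adjacency
indexes so that candidate-centred retrieval never scans the full graph.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import obonet

from .errors import (
    AmbiguousTermError,
    GmtParseError,
    IntegrityError,
    KgannoError,
    OntologyParseError,
    UnknownTermError,
)

IS_A = "IS_A"
PARTICIPATES_IN = "PARTICIPATES_IN"
COEXPRESSED_IN = "COEXPRESSED_IN"
HAS_ACTIVITY_IN = "HAS_ACTIVITY_IN"
IS_MARKER_FOR = "IS_MARKER_FOR"

RELATIONS = (IS_A, PARTICIPATES_IN, COEXPRESSED_IN, HAS_ACTIVITY_IN, IS_MARKER_FOR)

#: relation -> (source node kind, target node kind)
RELATION_ENDPOINTS = {
    IS_A: ("cell_type", "cell_type"),
    PARTICIPATES_IN: ("gene", "pathway"),
    COEXPRESSED_IN: ("gene", "gene"),
    HAS_ACTIVITY_IN: ("pathway", "cell_type"),
    IS_MARKER_FOR: ("gene", "cell_type"),
}

_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


@dataclass
class CellTypeNode:
    """An ontology term (e.g. ``CL:0000084`` / "T cell")."""

    id: str
    name: str
    synonyms: set[str] = field(default_factory=set)
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise IntegrityError(f"cell type {self.id!r} has an empty name")
        self.synonyms = {s for s in self.synonyms if s and s != self.name}


@dataclass(frozen=True)
class GeneNode:
    symbol: str

    def __post_init__(self) -> None:
        if not self.symbol or self.symbol != self.symbol.strip():
            raise IntegrityError(f"invalid gene symbol {self.symbol!r}")


@dataclass
class PathwayNode:
    """A named gene set ``S``."""

    id: str
    name: str
    members: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    relation: str
    attrs: tuple = ()  # sorted (key, value) pairs; hashable

    @property
    def attr_dict(self) -> dict:
        return dict(self.attrs)


def _freeze_attrs(attrs: dict | None) -> tuple:
    return tuple(sorted((attrs or {}).items()))


class KnowledgeGraph:
    """In-memory typed graph with per-relation adjacency indexes."""

    def __init__(self) -> None:
        self.cell_types: dict[str, CellTypeNode] = {}
        self.genes: dict[str, GeneNode] = {}
        self.pathways: dict[str, PathwayNode] = {}
        # relation -> source id -> list[Edge]
        self._fwd: dict[str, dict[str, list[Edge]]] = {r: {} for r in RELATIONS}
        # relation -> target id -> list[Edge]
        self._rev: dict[str, dict[str, list[Edge]]] = {r: {} for r in RELATIONS}
        self.provenance: dict = {}

    # ------------------------------------------------------------------ nodes
    def add_cell_type(self, node: CellTypeNode) -> None:
        if node.id in self.cell_types:
            raise IntegrityError(f"duplicate cell type id {node.id!r}")
        self.cell_types[node.id] = node

    def add_gene(self, symbol: str) -> GeneNode:
        symbol = symbol.strip()
        node = self.genes.get(symbol)
        if node is None:
            node = GeneNode(symbol)
            self.genes[symbol] = node
        return node

    def add_pathway(self, node: PathwayNode) -> None:
        if node.id in self.pathways:
            raise IntegrityError(f"duplicate pathway id {node.id!r}")
        if not node.members:
            raise IntegrityError(f"pathway {node.id!r} has no members")
        self.pathways[node.id] = node

    def _kind_of(self, node_id: str) -> str | None:
        if node_id in self.cell_types:
            return "cell_type"
        if node_id in self.genes:
            return "gene"
        if node_id in self.pathways:
            return "pathway"
        return None

    # ------------------------------------------------------------------ edges
    def add_edge(
        self, source: str, target: str, relation: str, attrs: dict | None = None
    ) -> Edge:
        if relation not in RELATIONS:
            raise IntegrityError(f"unknown relation {relation!r}")
        want_src, want_tgt = RELATION_ENDPOINTS[relation]
        if self._kind_of(source) != want_src:
            raise IntegrityError(
                f"{relation} source {source!r} is not a {want_src} node"
            )
        if self._kind_of(target) != want_tgt:
            raise IntegrityError(
                f"{relation} target {target!r} is not a {want_tgt} node"
            )
        edge = Edge(source, target, relation, _freeze_attrs(attrs))
        bucket = self._fwd[relation].setdefault(source, [])
        if edge in bucket:
            return edge  # exact duplicate: idempotent
        bucket.append(edge)
        self._rev[relation].setdefault(target, []).append(edge)
        return edge

    def edges(self, relation: str | None = None) -> Iterator[Edge]:
        rels = [relation] if relation else RELATIONS
        for rel in rels:
            for bucket in self._fwd[rel].values():
                yield from bucket

    def out_edges(self, node_id: str, relation: str) -> list[Edge]:
        return self._fwd[relation].get(node_id, [])

    def in_edges(self, node_id: str, relation: str) -> list[Edge]:
        return self._rev[relation].get(node_id, [])

    def edge_counts(self) -> dict[str, int]:
        return {
            r: sum(len(b) for b in self._fwd[r].values()) for r in RELATIONS
        }

    def node_counts(self) -> dict[str, int]:
        return {
            "cell_type": len(self.cell_types),
            "gene": len(self.genes),
            "pathway": len(self.pathways),
        }

    # -------------------------------------------------------------- hierarchy
    def parents(self, term_id: str) -> list[str]:
        """Direct IS_A parents of a cell-type term."""
        self._require_cell_type(term_id)
        return sorted(e.target for e in self.out_edges(term_id, IS_A))

    def children(self, term_id: str) -> list[str]:
        self._require_cell_type(term_id)
        return sorted(e.source for e in self.in_edges(term_id, IS_A))

    def descendants(self, root: str) -> set[str]:
        """Inclusive IS_A closure below ``root`` (the root plus every term
        from which ``root`` is reachable along IS_A chains)."""
        self._require_cell_type(root)
        seen = {root}
        frontier = [root]
        while frontier:
            node = frontier.pop()
            for edge in self.in_edges(node, IS_A):
                if edge.source not in seen:
                    seen.add(edge.source)
                    frontier.append(edge.source)
        return seen

    def ancestors(self, term_id: str) -> set[str]:
        """Inclusive IS_A closure above ``term_id``."""
        self._require_cell_type(term_id)
        seen = {term_id}
        frontier = [term_id]
        while frontier:
            node = frontier.pop()
            for edge in self.out_edges(node, IS_A):
                if edge.target not in seen:
                    seen.add(edge.target)
                    frontier.append(edge.target)
        return seen

    def depth(self, term_id: str) -> int:
        """Length of the longest IS_A chain from ``term_id`` up to a root."""
        self._require_cell_type(term_id)
        best = 0
        frontier = [(term_id, 0)]
        while frontier:
            node, d = frontier.pop()
            ups = self.out_edges(node, IS_A)
            if not ups:
                best = max(best, d)
            for edge in ups:
                frontier.append((edge.target, d + 1))
        return best

    def roots(self) -> list[str]:
        """Cell-type terms with no IS_A parent."""
        return sorted(
            t for t in self.cell_types if not self.out_edges(t, IS_A)
        )

    def _require_cell_type(self, term_id: str) -> None:
        if term_id not in self.cell_types:
            raise UnknownTermError(f"unknown cell type id {term_id!r}")

    # -------------------------------------------------------------- resolution
    def resolve_cell_type(self, query: str) -> str:
        """Resolve a cell-type reference to a term id.

        Resolution order: exact id, exact name, case-insensitive name or
        synonym.  An ambiguous match raises listing all hits.
        """
        if query in self.cell_types:
            return query
        by_name = [t.id for t in self.cell_types.values() if t.name == query]
        if len(by_name) == 1:
            return by_name[0]
        if len(by_name) > 1:
            raise AmbiguousTermError(f"{query!r} matches terms {sorted(by_name)}")
        q = query.strip().lower()
        loose = sorted(
            t.id
            for t in self.cell_types.values()
            if t.name.lower() == q or q in {s.lower() for s in t.synonyms}
        )
        if len(loose) == 1:
            return loose[0]
        if len(loose) > 1:
            raise AmbiguousTermError(f"{query!r} matches terms {loose}")
        raise UnknownTermError(f"cannot resolve cell type {query!r}")

    # -------------------------------------------------------------- validation
    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when sound)."""
        problems: list[str] = []
        for edge in self.edges():
            want_src, want_tgt = RELATION_ENDPOINTS[edge.relation]
            if self._kind_of(edge.source) != want_src:
                problems.append(f"dangling/mistyped source in {edge}")
            if self._kind_of(edge.target) != want_tgt:
                problems.append(f"dangling/mistyped target in {edge}")
        for pw in self.pathways.values():
            missing = pw.members - set(self.genes)
            if missing:
                problems.append(
                    f"pathway {pw.id} members missing gene nodes: {sorted(missing)}"
                )
        isa = nx.DiGraph(
            (e.source, e.target)
            for e in self.edges(IS_A)
            if not self.cell_types[e.source].obsolete
            and not self.cell_types[e.target].obsolete
        )
        if not nx.is_directed_acyclic_graph(isa):
            problems.append("IS_A subgraph over non-obsolete terms contains a cycle")
        return problems

    # -------------------------------------------------------------- merging
    def copy(self) -> "KnowledgeGraph":
        other = KnowledgeGraph()
        for ct in self.cell_types.values():
            other.add_cell_type(
                CellTypeNode(ct.id, ct.name, set(ct.synonyms), ct.obsolete)
            )
        for g in self.genes:
            other.add_gene(g)
        for pw in self.pathways.values():
            other.add_pathway(PathwayNode(pw.id, pw.name, set(pw.members)))
        for edge in self.edges():
            other.add_edge(edge.source, edge.target, edge.relation, edge.attr_dict)
        other.provenance = json.loads(json.dumps(self.provenance))
        return other


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def load_ontology(path: str | Path) -> KnowledgeGraph:
    """Load cell-type terms and IS_A edges from an OBO file.

    Obsolete terms are dropped (they cannot be annotation targets), along
    with any IS_A assertion touching them.  Only ``is_a`` relations are
    imported; ``part_of`` and other typedefs are ignored.
    """
    try:
        obo = obonet.read_obo(str(path), ignore_obsolete=False)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise OntologyParseError(f"cannot parse OBO file {path}: {exc}") from exc
    if len(obo) == 0:
        raise OntologyParseError(f"OBO file {path} contains no terms")

    kg = KnowledgeGraph()
    retained: set[str] = set()
    for term_id, data in obo.nodes(data=True):
        if str(data.get("is_obsolete", "false")).lower() == "true":
            continue
        name = data.get("name")
        if not name:
            raise OntologyParseError(
                f"term stanza {term_id!r} in {path} has no name"
            )
        synonyms = set()
        for line in data.get("synonym", []):
            m = _SYNONYM_RE.match(line)
            if m:
                synonyms.add(m.group(1))
        kg.add_cell_type(CellTypeNode(term_id, name, synonyms))
        retained.add(term_id)

    for child, data in obo.nodes(data=True):
        if child not in retained:
            continue
        for parent in data.get("is_a", []):
            if parent in retained:
                kg.add_edge(child, parent, IS_A)

    isa = nx.DiGraph((e.source, e.target) for e in kg.edges(IS_A))
    if not nx.is_directed_acyclic_graph(isa):
        cycle = nx.find_cycle(isa)
        raise IntegrityError(f"cyclic is_a chain among retained terms: {cycle}")
    kg.provenance.setdefault("sources", {})["ontology"] = str(path)
    return kg


def load_gene_sets(path: str | Path, into: KnowledgeGraph | None = None) -> KnowledgeGraph:
    """Load pathways from a GMT file into a graph.

    Each line is ``name<TAB>description<TAB>gene...``; duplicate genes within
    a line are collapsed to one membership edge.  Gene symbols are matched
    case-sensitively after whitespace stripping.
    """
    kg = into if into is not None else KnowledgeGraph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description = fields[0].strip(), fields[1].strip()
            members: list[str] = []
            for g in fields[2:]:
                g = g.strip()
                if g and g not in members:
                    members.append(g)
            if not members:
                raise GmtParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            pathway = PathwayNode(id=name, name=description or name, members=set(members))
            kg.add_pathway(pathway)
            for g in members:
                kg.add_gene(g)
                kg.add_edge(g, name, PARTICIPATES_IN)
    kg.provenance.setdefault("sources", {})["gene_sets"] = str(path)
    return kg


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def export_graph(kg: KnowledgeGraph, path: str | Path, format: str = "tsv") -> None:
    """Serialize a graph to ``GraphML`` or a two-file TSV pair.

    For ``tsv`` the path is a directory receiving ``nodes.tsv`` (id, type,
    name, synonyms pipe-joined) and ``edges.tsv`` (source, relation, target,
    JSON-encoded attrs).  Pathway membership is recovered on import from
    PARTICIPATES_IN edges.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.MultiDiGraph()
        for ct in kg.cell_types.values():
            g.add_node(
                ct.id,
                kind="cell_type",
                name=ct.name,
                synonyms="|".join(sorted(ct.synonyms)),
                obsolete=ct.obsolete,
            )
        for gene in kg.genes.values():
            g.add_node(gene.symbol, kind="gene", name=gene.symbol)
        for pw in kg.pathways.values():
            g.add_node(pw.id, kind="pathway", name=pw.name)
        for edge in kg.edges():
            g.add_edge(
                edge.source,
                edge.target,
                relation=edge.relation,
                attrs=json.dumps(edge.attr_dict, sort_keys=True),
            )
        nx.write_graphml(g, path)
    elif format == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "nodes.tsv", "w") as fh:
            fh.write("id\ttype\tname\tsynonyms\n")
            for ct in sorted(kg.cell_types.values(), key=lambda n: n.id):
                fh.write(
                    f"{ct.id}\tcell_type\t{ct.name}\t"
                    f"{'|'.join(sorted(ct.synonyms))}\n"
                )
            for sym in sorted(kg.genes):
                fh.write(f"{sym}\tgene\t{sym}\t\n")
            for pw in sorted(kg.pathways.values(), key=lambda n: n.id):
                fh.write(f"{pw.id}\tpathway\t{pw.name}\t\n")
        with open(path / "edges.tsv", "w") as fh:
            fh.write("source\trelation\ttarget\tattrs\n")
            key = lambda e: (e.relation, e.source, e.target, e.attrs)
            for edge in sorted(kg.edges(), key=key):
                fh.write(
                    f"{edge.source}\t{edge.relation}\t{edge.target}\t"
                    f"{json.dumps(edge.attr_dict, sort_keys=True)}\n"
                )
    else:
        raise KgannoError(f"unsupported export format {format!r}")


def import_graph(path: str | Path, format: str = "tsv") -> KnowledgeGraph:
    """Inverse of :func:`export_graph`."""
    path = Path(path)
    kg = KnowledgeGraph()
    nodes: list[tuple[str, str, str, str, bool]] = []
    edges: list[tuple[str, str, str, dict]] = []
    if format == "graphml":
        g = nx.read_graphml(path)
        for node_id, data in g.nodes(data=True):
            nodes.append(
                (
                    node_id,
                    data["kind"],
                    data.get("name", node_id),
                    data.get("synonyms", ""),
                    bool(data.get("obsolete", False)),
                )
            )
        for src, tgt, data in g.edges(data=True):
            edges.append((src, tgt, data["relation"], json.loads(data.get("attrs", "{}"))))
    elif format == "tsv":
        with open(path / "nodes.tsv") as fh:
            next(fh)
            for line in fh:
                node_id, kind, name, synonyms = line.rstrip("\n").split("\t")
                nodes.append((node_id, kind, name, synonyms, False))
        with open(path / "edges.tsv") as fh:
            next(fh)
            for line in fh:
                src, rel, tgt, attrs = line.rstrip("\n").split("\t")
                edges.append((src, tgt, rel, json.loads(attrs)))
    else:
        raise KgannoError(f"unsupported import format {format!r}")

    pathway_nodes: dict[str, str] = {}
    for node_id, kind, name, synonyms, obsolete in nodes:
        if kind == "cell_type":
            syns = set(synonyms.split("|")) - {""} if synonyms else set()
            kg.add_cell_type(CellTypeNode(node_id, name, syns, obsolete))
        elif kind == "gene":
            kg.add_gene(node_id)
        elif kind == "pathway":
            pathway_nodes[node_id] = name
        else:
            raise KgannoError(f"unknown node kind {kind!r} for {node_id!r}")
    # pathway membership is defined by PARTICIPATES_IN edges
    members: dict[str, set[str]] = {p: set() for p in pathway_nodes}
    for src, tgt, rel, _ in edges:
        if rel == PARTICIPATES_IN:
            members.setdefault(tgt, set()).add(src)
    for pw_id, name in pathway_nodes.items():
        kg.add_pathway(PathwayNode(pw_id, name, members[pw_id]))
    for src, tgt, rel, attrs in edges:
        kg.add_edge(src, tgt, rel, attrs)
    return kg
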