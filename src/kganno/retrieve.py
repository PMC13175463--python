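"""Evidence retrieval against the knowledge graph.

Two query shapes back the annotation pipeline:

* a *global* candidate-centred query (major-type arbitration) that collects,
  for each candidate cell type, its immediate ontology context, the
  marker → pathway → cell-type chains supporting it, and marker pairs
  co-expressed within its lineage;
* a *focused* subgraph query (subtype resolution) restricted to a confirmed
  major type and its IS_A descendants.  Co-expression edges are deliberately
  excluded from the focused domain: they are too unspecific to separate
  closely related subtypes.

Both queries are index lookups anchored on the candidates and the marker
genes — never full-graph scans — and neither mutates the graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import RetrievalError, UnknownTermError, AmbiguousTermError
from .graph import (
    COEXPRESSED_IN,
    HAS_ACTIVITY_IN,
    IS_A,
    IS_MARKER_FOR,
    PARTICIPATES_IN,
    KnowledgeGraph,
)

log = logging.getLogger(__name__)


@dataclass
class EvidenceBundle:
    """Per-candidate qualitative evidence for major-type arbitration."""

    candidate: str  # resolved term id
    candidate_name: str
    parents: list[str] = field(default_factory=list)  # parent names
    children: list[str] = field(default_factory=list)  # child names
    #: (marker gene, pathway id, cell-type id) chains via
    #: PARTICIPATES_IN then HAS_ACTIVITY_IN
    pathway_links: list[tuple[str, str, str]] = field(default_factory=list)
    #: marker pairs co-expressed with context inside the candidate's lineage
    coexpression_pairs: list[tuple[str, str]] = field(default_factory=list)
    #: IS_MARKER_FOR hits, populated only when that relation is enabled
    marker_links: list[str] = field(default_factory=list)
    unresolved_markers: list[str] = field(default_factory=list)

    @property
    def pathway_link_count(self) -> int:
        return len(self.pathway_links)

    @property
    def coexpression_support(self) -> int:
        return len(self.coexpression_pairs)

    @property
    def has_evidence(self) -> bool:
        return bool(self.pathway_links or self.coexpression_pairs or self.marker_links)


@dataclass
class FocusedSubgraph:
    """The subtype-resolution domain: a major type plus its descendants."""

    major: str
    domain: set[str]
    candidate_subtypes: set[str]
    #: subtype id -> sorted (marker, pathway) chains anchoring it
    marker_chains: dict[str, list[tuple[str, str]]]
    retained_edges: list[tuple[str, str, str]]  # (source, relation, target)
    node_count: int = 0
    edge_count: int = 0


def _resolve_candidates(kg: KnowledgeGraph, candidates: list[str]) -> list[tuple[str, str]]:
    """Resolve (query, term id) pairs; unresolvable entries are dropped."""
    resolved: list[tuple[str, str]] = []
    for query in candidates:
        try:
            resolved.append((query, kg.resolve_cell_type(query)))
        except (UnknownTermError, AmbiguousTermError) as exc:
            log.warning("candidate %r not resolved: %s", query, exc)
    if not resolved:
        raise RetrievalError(f"no candidate among {candidates!r} resolves in the graph")
    return resolved


def global_evidence(
    kg: KnowledgeGraph,
    candidates: list[str],
    markers: list[str],
    include_marker_edges: bool = False,
) -> list[EvidenceBundle]:
    """Collect one evidence bundle per candidate major type.

    Lookups touch only the candidate nodes, their direct IS_A neighbours and
    the marker-anchored adjacency lists.  Markers missing from the graph are
    recorded on each bundle rather than raised.  ``IS_MARKER_FOR`` hits are
    reported only when explicitly enabled; that relation is off by default
    because direct marker assertions tend to crowd out pathway evidence.
    """
    if not markers:
        raise RetrievalError("marker list is empty")
    resolved = _resolve_candidates(kg, candidates)
    known = [m for m in markers if m in kg.genes]
    unresolved = [m for m in markers if m not in kg.genes]
    if unresolved:
        log.info("markers absent from graph: %s", unresolved)

    # marker-anchored pathway adjacency, shared across candidates
    marker_pathways: dict[str, list[str]] = {
        m: sorted(e.target for e in kg.out_edges(m, PARTICIPATES_IN)) for m in known
    }

    bundles: list[EvidenceBundle] = []
    for _, term_id in resolved:
        node = kg.cell_types[term_id]
        bundle = EvidenceBundle(
            candidate=term_id,
            candidate_name=node.name,
            parents=[kg.cell_types[p].name for p in kg.parents(term_id)],
            children=[kg.cell_types[c].name for c in kg.children(term_id)],
            unresolved_markers=list(unresolved),
        )
        # chains may land on the candidate itself or anywhere in its lineage:
        # activity edges inferred at subtype resolution still support the
        # major-type hypothesis
        closure = kg.descendants(term_id)
        for marker in known:
            for pw in marker_pathways[marker]:
                for edge in kg.out_edges(pw, HAS_ACTIVITY_IN):
                    if edge.target in closure:
                        bundle.pathway_links.append((marker, pw, edge.target))
        bundle.pathway_links.sort()
        seen_pairs: set[tuple[str, str]] = set()
        for marker in known:
            for edge in kg.out_edges(marker, COEXPRESSED_IN):
                other = edge.target
                if other in known and edge.attr_dict.get("context") in closure:
                    seen_pairs.add((min(marker, other), max(marker, other)))
            for edge in kg.in_edges(marker, COEXPRESSED_IN):
                other = edge.source
                if other in known and edge.attr_dict.get("context") in closure:
                    seen_pairs.add((min(marker, other), max(marker, other)))
        bundle.coexpression_pairs = sorted(seen_pairs)

        if include_marker_edges:
            bundle.marker_links = sorted(
                e.source
                for m in known
                for e in kg.out_edges(m, IS_MARKER_FOR)
                if e.target == term_id
            )
        bundles.append(bundle)
    return bundles


def subgraph_domain(
    kg: KnowledgeGraph, major: str, markers: list[str]
) -> FocusedSubgraph:
    """Build the focused subtype-resolution domain for a confirmed major type.

    The domain is the inclusive IS_A closure under the major type; candidate
    subtypes are the domain members reached by a marker → pathway →
    cell-type chain.  Retained edges are the IS_A edges inside the domain,
    the HAS_ACTIVITY_IN edges landing in it from marker-linked pathways, and
    the PARTICIPATES_IN edges from markers into those pathways.
    Co-expression edges are excluded by construction.
    """
    major_id = kg.resolve_cell_type(major)
    domain = kg.descendants(major_id)

    known = [m for m in markers if m in kg.genes]
    marker_chains: dict[str, list[tuple[str, str]]] = {}
    retained: list[tuple[str, str, str]] = []
    linked_pathways: set[tuple[str, str]] = set()  # (marker, pathway)

    for term in sorted(domain):
        for edge in kg.out_edges(term, IS_A):
            if edge.target in domain:
                retained.append((term, IS_A, edge.target))

    for marker in sorted(known):
        for pe in kg.out_edges(marker, PARTICIPATES_IN):
            pw = pe.target
            for ae in kg.out_edges(pw, HAS_ACTIVITY_IN):
                if ae.target in domain:
                    marker_chains.setdefault(ae.target, []).append((marker, pw))
                    if (marker, pw) not in linked_pathways:
                        linked_pathways.add((marker, pw))
                        retained.append((marker, PARTICIPATES_IN, pw))
                    retained.append((pw, HAS_ACTIVITY_IN, ae.target))

    retained = sorted(set(retained))
    for chains in marker_chains.values():
        chains.sort()

    cell_nodes = set(domain)
    pathway_nodes = {pw for _, pw in linked_pathways}
    gene_nodes = {m for m, _ in linked_pathways}
    sub = FocusedSubgraph(
        major=major_id,
        domain=domain,
        candidate_subtypes=set(marker_chains),
        marker_chains=marker_chains,
        retained_edges=retained,
        node_count=len(cell_nodes | pathway_nodes | gene_nodes),
        edge_count=len(retained),
    )
    log.info(
        "focused subgraph for %s: %d nodes, %d edges (%d candidate subtypes)",
        major_id,
        sub.node_count,
        sub.edge_count,
        len(sub.candidate_subtypes),
    )
    return sub


# ---------------------------------------------------------------------------
# prompt-ready rendering
# ---------------------------------------------------------------------------

def summarize_evidence(obj: EvidenceBundle | FocusedSubgraph, kg: KnowledgeGraph | None = None) -> str:
    """Deterministic, token-frugal key:value rendering for prompt injection.

    The same object always renders to byte-identical text; links appear
    sorted by marker then pathway id.
    """
    lines: list[str] = []
    if isinstance(obj, EvidenceBundle):
        lines.append(f"candidate: {obj.candidate_name} [{obj.candidate}]")
        lines.append(f"ontology_parents: {', '.join(obj.parents) or 'none'}")
        lines.append(f"ontology_children: {', '.join(obj.children) or 'none'}")
        if obj.pathway_links:
            lines.append(f"pathway_links ({len(obj.pathway_links)}):")
            for marker, pw, ct in obj.pathway_links:
                lines.append(f"  {marker} -> {pw} -> {ct}")
        else:
            lines.append("pathway_links (0): none")
        if obj.coexpression_pairs:
            lines.append(f"coexpression_pairs ({len(obj.coexpression_pairs)}):")
            for a, b in obj.coexpression_pairs:
                lines.append(f"  {a} ~ {b}")
        else:
            lines.append("coexpression_pairs (0): none")
        if obj.marker_links:
            lines.append(f"marker_links ({len(obj.marker_links)}): "
                         + ", ".join(obj.marker_links))
        if not obj.has_evidence:
            lines.append("note: no KG evidence for this candidate")
    elif isinstance(obj, FocusedSubgraph):
        name = kg.cell_types[obj.major].name if kg else obj.major
        lines.append(f"major_type: {name} [{obj.major}]")
        lines.append(f"domain_size: {len(obj.domain)} cell types")
        if obj.candidate_subtypes:
            lines.append(f"candidate_subtypes ({len(obj.candidate_subtypes)}):")
            for term in sorted(obj.candidate_subtypes):
                tname = kg.cell_types[term].name if kg else term
                chains = "; ".join(f"{m} via {p}" for m, p in obj.marker_chains[term])
                lines.append(f"  {tname} [{term}]: {chains}")
        else:
            lines.append("candidate_subtypes (0): no KG evidence below the major type")
    else:
        raise TypeError(f"cannot summarize {type(obj).__name__}")
    return "\n".join(lines)
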