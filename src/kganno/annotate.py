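"""Three-stage hierarchical annotation.

Stage 1 asks the backend (a language model, or the deterministic mock used
for offline testing) to propose ``k`` candidate major lineages from a
cluster's marker genes.  Stage 2 arbitrates between those candidates using
global knowledge-graph evidence; the decision must come from the proposed
candidates (strict mode), and when the cluster is flagged as a possible
mixture, the arbiter may confirm two components.  Stage 3 resolves the most
specific subtype inside the focused subgraph domain of the confirmed major
type, falling back to the major type itself when the graph offers no
subtype-level evidence; for mixtures each component is resolved
independently, with the other component's markers flagged as background.

All backends satisfy the same ``complete(payload, temperature, seed)``
contract; the mock backend is a pure function of its inputs, which makes
every pipeline run reproducible and order-stable regardless of the worker
count.
"""

from __future__ import annotations

import json
import logging
import re
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Protocol

from .errors import BackendError, ContractViolationError, StageError
from .graph import KnowledgeGraph
from .prompts import render_stage1, render_stage2, render_stage3
from .retrieve import (
    EvidenceBundle,
    FocusedSubgraph,
    global_evidence,
    subgraph_domain,
    summarize_evidence,
)

log = logging.getLogger(__name__)

_ID_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*:\d+$")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ClusterInput:
    cluster_id: str
    markers: list[str]
    mixed_hint: bool = False

    def __post_init__(self) -> None:
        deduped: list[str] = []
        for m in self.markers:
            m = m.strip()
            if m and m not in deduped:
                deduped.append(m)
        if not deduped:
            raise ValueError(f"cluster {self.cluster_id!r} has no markers")
        self.markers = deduped
        self.cluster_id = str(self.cluster_id)


@dataclass(frozen=True)
class CandidateProposal:
    name: str
    ontology_id: str
    reasoning: str
    rank: int


@dataclass
class MajorDecision:
    cluster_id: str
    name: str
    ontology_id: str
    reasoning: str
    is_mixture: bool = False
    components: list[tuple[str, str]] = field(default_factory=list)  # (name, id)

    def __post_init__(self) -> None:
        if self.is_mixture:
            if len(self.components) != 2:
                raise ContractViolationError(
                    "a mixture decision must name exactly 2 components"
                )
        elif self.components and self.components != [(self.name, self.ontology_id)]:
            raise ContractViolationError("a single decision has exactly one component")


@dataclass
class FinalAnnotation:
    cluster_id: str
    name: str
    ontology_id: str
    reasoning: str | None
    positive_markers: list[str] | None
    major: MajorDecision
    components: list["FinalAnnotation"] | None = None  # populated for mixtures

    def to_record(self, explain: bool = True) -> dict:
        rec: dict = {
            "cluster_id": self.cluster_id,
            "major": {"name": self.major.name, "id": self.major.ontology_id},
            "final": {"name": self.name, "id": self.ontology_id},
        }
        if explain:
            if self.reasoning is not None:
                rec["reasoning"] = self.reasoning
            if self.positive_markers is not None:
                rec["positive_markers"] = self.positive_markers
        if self.components:
            rec["mixture"] = [c.to_record(explain) for c in self.components]
        return rec


@dataclass
class AnnotationRun:
    annotations: list[FinalAnnotation]
    errors: list[dict]

    def to_jsonl(self, explain: bool = True) -> str:
        return "\n".join(
            json.dumps(a.to_record(explain), sort_keys=True) for a in self.annotations
        )


@dataclass
class AnnotateConfig:
    candidates_k: int = 3
    n_markers: int = 10
    temperature: float = 0.5
    workers: int = 4
    batch_size: int = 4
    explain: bool = True
    prompt_style: str = "neutral"
    strict_candidates: bool = True
    include_marker_edges: bool = False
    retries: int = 2
    seed: int = 0


# ---------------------------------------------------------------------------
# backend contract and the deterministic mock
# ---------------------------------------------------------------------------

class Backend(Protocol):
    """Chat-completion-style backend: structured payload in, dict out."""

    def complete(self, payload: dict, temperature: float = 0.5,
                 seed: int | None = None) -> dict: ...


def marker_fingerprint(markers: list[str]) -> str:
    """Order-insensitive key for rulebook lookups."""
    return ",".join(sorted(set(markers)))


def _stage2_key(cand: dict) -> tuple:
    """Evidence-following preference: more pathway links, then more
    co-expression support, then the better (lower) stage-1 rank."""
    return (
        cand.get("pathway_link_count", 0),
        cand.get("coexpression_support", 0),
        -cand.get("rank", 99),
    )


def _stage3_key(cand: dict) -> tuple:
    """More marker chains, then deeper in the hierarchy, then lexicographically
    smaller term id (realised as a reversed-sort key)."""
    return (cand.get("chain_count", 0), cand.get("depth", 0))


class MockBackend:
    """Deterministic stand-in for a remote model.

    Stage 1 answers from a *rulebook* keyed on the marker-set fingerprint;
    stages 2 and 3 follow fixed argmax rules over the evidence supplied in
    the payload, emulating an arbiter that follows the graph evidence.
    Identical inputs always produce identical outputs.
    """

    identity = "mock"
    supports_batch = True

    def __init__(self, rulebook: dict[str, list] | None = None,
                 default: list | None = None):
        self.rulebook = dict(rulebook or {})
        self.default = default

    def complete(self, payload: dict, temperature: float = 0.5,
                 seed: int | None = None) -> dict:
        stage = payload.get("stage")
        if stage == 1:
            if "clusters" in payload:  # batched form
                return {
                    "results": {
                        str(c["cluster_id"]): self._stage1(c) for c in payload["clusters"]
                    }
                }
            return self._stage1(payload)
        if stage == 2:
            return self._stage2(payload)
        if stage == 3:
            return self._stage3(payload)
        raise BackendError(f"unknown stage in payload: {stage!r}")

    def _stage1(self, payload: dict) -> dict:
        fp = marker_fingerprint(payload["markers"])
        entry = self.rulebook.get(fp, self.default)
        if entry is None:
            raise BackendError(
                f"no rulebook entry for marker fingerprint {fp!r} and no default"
            )
        k = payload.get("k", 3)
        cands = [
            {
                "name": name,
                "ontology_id": term_id,
                "reasoning": f"rulebook proposal for {payload['cluster_id']}",
                "rank": i + 1,
            }
            for i, (name, term_id) in enumerate(entry[:k])
        ]
        return {"candidates": cands}

    def _stage2(self, payload: dict) -> dict:
        cands = payload["candidates"]
        ordered = sorted(cands, key=_stage2_key, reverse=True)
        if payload.get("mixed_hint"):
            supported = [c for c in ordered if c.get("pathway_link_count", 0) > 0]
            if len(supported) >= 2:
                comps = sorted(supported[:2], key=lambda c: c["rank"])
                return {
                    "is_mixture": True,
                    "components": [
                        {"name": c["name"], "ontology_id": c["ontology_id"]}
                        for c in comps
                    ],
                    "reasoning": "both lineages carry positive KG evidence",
                }
        best = ordered[0]
        return {
            "name": best["name"],
            "ontology_id": best["ontology_id"],
            "reasoning": (
                f"selected on KG evidence: {best.get('pathway_link_count', 0)} pathway "
                f"links, {best.get('coexpression_support', 0)} co-expression pairs"
            ),
            "is_mixture": False,
        }

    def _stage3(self, payload: dict) -> dict:
        cands = payload["candidates"]
        best = sorted(
            cands, key=lambda c: (*(-v for v in _stage3_key(c)), c["ontology_id"])
        )[0]
        return {
            "name": best["name"],
            "ontology_id": best["ontology_id"],
            "reasoning": (
                f"subtype with strongest marker-chain support "
                f"({best.get('chain_count', 0)} chains)"
            ),
            "positive_markers": list(best.get("markers", [])),
        }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _check_identity(kg: KnowledgeGraph, name: str, term_id: str, strict: bool,
                    where: str) -> str:
    """Guard against malformed or hallucinated ontology ids.

    Returns the (possibly corrected) display name.
    """
    if not _ID_RE.match(term_id):
        raise ContractViolationError(f"{where}: malformed ontology id {term_id!r}")
    node = kg.cell_types.get(term_id)
    if node is not None and node.name != name and name not in node.synonyms:
        msg = f"{where}: id {term_id} names {node.name!r} in the graph, not {name!r}"
        if strict:
            raise ContractViolationError(msg)
        log.warning("%s; using the graph name", msg)
        return node.name
    return name


def stage1_propose(
    backend: Backend,
    cluster: ClusterInput,
    k: int = 3,
    temperature: float = 0.5,
    seed: int | None = None,
    retries: int = 2,
) -> list[CandidateProposal]:
    """Propose ``k`` ranked candidate major lineages for one cluster."""
    if not 1 <= k <= 5:
        raise ValueError("candidate count k must be in 1..5")
    payload = {
        "stage": 1,
        "cluster_id": cluster.cluster_id,
        "markers": cluster.markers,
        "k": k,
        "prompt": render_stage1(cluster.cluster_id, cluster.markers, k,
                                cluster.mixed_hint),
    }
    last_error = None
    for attempt in range(retries + 1):
        try:
            response = backend.complete(payload, temperature=temperature, seed=seed)
            return parse_stage1_response(response, k)
        except BackendError:
            raise
        except Exception as exc:  # malformed response: retry
            last_error = exc
            log.warning(
                "stage 1 parse failure for cluster %s (attempt %d/%d): %s",
                cluster.cluster_id, attempt + 1, retries + 1, exc,
            )
    raise StageError(1, cluster.cluster_id, f"invalid response after retries: {last_error}")


def parse_stage1_response(response: dict, k: int) -> list[CandidateProposal]:
    cands = response["candidates"]
    if len(cands) != k:
        raise ValueError(f"expected {k} candidates, got {len(cands)}")
    proposals = [
        CandidateProposal(
            name=str(c["name"]),
            ontology_id=str(c["ontology_id"]),
            reasoning=str(c.get("reasoning", "")),
            rank=int(c["rank"]),
        )
        for c in cands
    ]
    if sorted(p.rank for p in proposals) != list(range(1, k + 1)):
        raise ValueError("candidate ranks must be exactly 1..k")
    return sorted(proposals, key=lambda p: p.rank)


def stage2_arbitrate(
    backend: Backend,
    cluster: ClusterInput,
    proposals: list[CandidateProposal],
    evidence: list[EvidenceBundle],
    prompt_style: str = "neutral",
    strict: bool = True,
    kg: KnowledgeGraph | None = None,
    temperature: float = 0.5,
    seed: int | None = None,
) -> MajorDecision:
    """Arbitrate the stage-1 candidates against global graph evidence."""
    if len(evidence) != len(proposals):
        raise ValueError("need exactly one evidence bundle per proposal")
    by_id = {p.ontology_id: p for p in proposals}
    by_name = {p.name: p for p in proposals}
    cand_block = "\n".join(
        f"{p.rank}. {p.name} [{p.ontology_id}]: {p.reasoning}" for p in proposals
    )
    evidence_block = "\n\n".join(summarize_evidence(b) for b in evidence)
    payload = {
        "stage": 2,
        "cluster_id": cluster.cluster_id,
        "markers": cluster.markers,
        "mixed_hint": cluster.mixed_hint,
        "candidates": [
            {
                "name": p.name,
                "ontology_id": p.ontology_id,
                "rank": p.rank,
                "reasoning": p.reasoning,
                "pathway_link_count": b.pathway_link_count,
                "coexpression_support": b.coexpression_support,
            }
            for p, b in zip(proposals, evidence)
        ],
        "prompt": render_stage2(cluster.cluster_id, cluster.markers, cand_block,
                                evidence_block, prompt_style),
    }
    response = backend.complete(payload, temperature=temperature, seed=seed)

    def _closure_check(name: str, term_id: str) -> None:
        if term_id in by_id or name in by_name:
            return
        msg = (
            f"stage 2 decision {name!r} [{term_id}] is not among the stage-1 "
            f"candidates for cluster {cluster.cluster_id}"
        )
        if strict:
            raise ContractViolationError(msg)
        log.warning("%s (lenient mode: accepted)", msg)

    if response.get("is_mixture"):
        comps = response.get("components", [])
        for c in comps:
            _closure_check(c["name"], c["ontology_id"])
            if kg is not None:
                c["name"] = _check_identity(kg, c["name"], c["ontology_id"], strict,
                                            f"cluster {cluster.cluster_id} stage 2")
        decision = MajorDecision(
            cluster_id=cluster.cluster_id,
            name=" + ".join(c["name"] for c in comps),
            ontology_id=comps[0]["ontology_id"] if comps else "",
            reasoning=str(response.get("reasoning", "")),
            is_mixture=True,
            components=[(c["name"], c["ontology_id"]) for c in comps],
        )
        return decision

    name, term_id = str(response["name"]), str(response["ontology_id"])
    _closure_check(name, term_id)
    if kg is not None:
        name = _check_identity(kg, name, term_id, strict,
                               f"cluster {cluster.cluster_id} stage 2")
    return MajorDecision(
        cluster_id=cluster.cluster_id,
        name=name,
        ontology_id=term_id,
        reasoning=str(response.get("reasoning", "")),
    )


def stage3_subtype(
    backend: Backend,
    cluster: ClusterInput,
    decision: MajorDecision,
    subgraph: FocusedSubgraph,
    kg: KnowledgeGraph,
    markers: list[str] | None = None,
    background_markers: list[str] | None = None,
    strict: bool = True,
    temperature: float = 0.5,
    seed: int | None = None,
) -> FinalAnnotation:
    """Resolve the most specific subtype inside the focused domain.

    When the domain offers no candidate subtype the major type is returned
    unchanged — the graph cannot refine what it has no evidence about.
    """
    markers = markers if markers is not None else cluster.markers
    major_name = kg.cell_types[subgraph.major].name
    if not subgraph.candidate_subtypes:
        return FinalAnnotation(
            cluster_id=cluster.cluster_id,
            name=major_name,
            ontology_id=subgraph.major,
            reasoning="no subtype-level evidence in the focused subgraph; "
                      "keeping the confirmed major type",
            positive_markers=[],
            major=decision,
        )
    candidates = [
        {
            "name": kg.cell_types[term].name,
            "ontology_id": term,
            "chain_count": len(subgraph.marker_chains[term]),
            "depth": kg.depth(term),
            "markers": sorted({m for m, _ in subgraph.marker_chains[term]}),
        }
        for term in sorted(subgraph.candidate_subtypes)
    ]
    payload = {
        "stage": 3,
        "cluster_id": cluster.cluster_id,
        "markers": markers,
        "major": {"name": major_name, "ontology_id": subgraph.major},
        "candidates": candidates,
        "prompt": render_stage3(
            cluster.cluster_id, markers, major_name, subgraph.major,
            summarize_evidence(subgraph, kg), background_markers,
        ),
    }
    response = backend.complete(payload, temperature=temperature, seed=seed)
    name, term_id = str(response["name"]), str(response["ontology_id"])
    if strict and term_id not in subgraph.candidate_subtypes:
        raise ContractViolationError(
            f"stage 3 subtype {term_id} is outside the focused domain for "
            f"cluster {cluster.cluster_id}"
        )
    name = _check_identity(kg, name, term_id, strict,
                           f"cluster {cluster.cluster_id} stage 3")
    return FinalAnnotation(
        cluster_id=cluster.cluster_id,
        name=name,
        ontology_id=term_id,
        reasoning=str(response.get("reasoning", "")),
        positive_markers=[str(m) for m in response.get("positive_markers", [])],
        major=decision,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _component_markers(
    kg: KnowledgeGraph, markers: list[str], component_id: str
) -> list[str]:
    """Markers with a pathway chain into the component's lineage closure."""
    sub = subgraph_domain(kg, component_id, markers)
    supporting = sorted({m for chains in sub.marker_chains.values() for m, _ in chains})
    return supporting


def _annotate_one(
    backend: Backend,
    kg: KnowledgeGraph,
    cluster: ClusterInput,
    config: AnnotateConfig,
    proposals: list[CandidateProposal] | None = None,
) -> FinalAnnotation:
    if proposals is None:
        proposals = stage1_propose(
            backend, cluster, config.candidates_k, config.temperature,
            config.seed, config.retries,
        )
    bundles = global_evidence(
        kg,
        [p.ontology_id for p in proposals],
        cluster.markers,
        include_marker_edges=config.include_marker_edges,
    )
    decision = stage2_arbitrate(
        backend, cluster, proposals, bundles,
        prompt_style=config.prompt_style,
        strict=config.strict_candidates,
        kg=kg,
        temperature=config.temperature,
        seed=config.seed,
    )
    if decision.is_mixture:
        components: list[FinalAnnotation] = []
        comp_markers = {
            cid: _component_markers(kg, cluster.markers, cid)
            for _, cid in decision.components
        }
        for comp_name, comp_id in decision.components:
            own = comp_markers[comp_id] or cluster.markers
            background = sorted(
                set().union(
                    *(comp_markers[other] for _, other in decision.components
                      if other != comp_id)
                )
                - set(own)
            )
            sub = subgraph_domain(kg, comp_id, own)
            comp_decision = MajorDecision(
                cluster_id=cluster.cluster_id,
                name=comp_name,
                ontology_id=comp_id,
                reasoning=decision.reasoning,
            )
            components.append(
                stage3_subtype(
                    backend, cluster, comp_decision, sub, kg,
                    markers=own, background_markers=background,
                    strict=config.strict_candidates,
                    temperature=config.temperature, seed=config.seed,
                )
            )
        lead = components[0]
        return FinalAnnotation(
            cluster_id=cluster.cluster_id,
            name=lead.name,
            ontology_id=lead.ontology_id,
            reasoning=decision.reasoning,
            positive_markers=lead.positive_markers,
            major=decision,
            components=components,
        )
    sub = subgraph_domain(kg, decision.ontology_id, cluster.markers)
    return stage3_subtype(
        backend, cluster, decision, sub, kg,
        strict=config.strict_candidates,
        temperature=config.temperature, seed=config.seed,
    )


def _batched_stage1(
    backend: Backend,
    clusters: list[ClusterInput],
    config: AnnotateConfig,
) -> dict[str, list[CandidateProposal] | Exception]:
    """Run stage 1 in joint batches when the backend supports it."""
    out: dict[str, list[CandidateProposal] | Exception] = {}
    if not getattr(backend, "supports_batch", False) or config.batch_size <= 1:
        for cluster in clusters:
            try:
                out[cluster.cluster_id] = stage1_propose(
                    backend, cluster, config.candidates_k, config.temperature,
                    config.seed, config.retries,
                )
            except Exception as exc:
                out[cluster.cluster_id] = exc
        return out
    for i in range(0, len(clusters), config.batch_size):
        batch = clusters[i : i + config.batch_size]
        payload = {
            "stage": 1,
            "clusters": [
                {
                    "stage": 1,
                    "cluster_id": c.cluster_id,
                    "markers": c.markers,
                    "k": config.candidates_k,
                    "prompt": render_stage1(c.cluster_id, c.markers,
                                            config.candidates_k, c.mixed_hint),
                }
                for c in batch
            ],
        }
        try:
            response = backend.complete(payload, temperature=config.temperature,
                                        seed=config.seed)
            results = response["results"]
        except Exception:
            # joint call failed: fall back to per-cluster calls so one bad
            # cluster cannot sink its batch mates
            for cluster in batch:
                try:
                    out[cluster.cluster_id] = stage1_propose(
                        backend, cluster, config.candidates_k, config.temperature,
                        config.seed, config.retries,
                    )
                except Exception as exc:
                    out[cluster.cluster_id] = exc
            continue
        for cluster in batch:
            try:
                out[cluster.cluster_id] = parse_stage1_response(
                    results[cluster.cluster_id], config.candidates_k
                )
            except Exception as exc:
                out[cluster.cluster_id] = StageError(
                    1, cluster.cluster_id, f"batched response invalid: {exc}"
                )
    return out


def annotate(
    backend: Backend,
    kg: KnowledgeGraph,
    clusters: list[ClusterInput],
    config: AnnotateConfig | None = None,
) -> AnnotationRun:
    """Run the full three-stage pipeline over a set of clusters.

    Per-cluster failures are isolated into an error manifest; successful
    annotations are returned sorted by cluster id so output is stable across
    worker counts and completion order.
    """
    config = config or AnnotateConfig()
    proposals = _batched_stage1(backend, clusters, config)

    annotations: list[FinalAnnotation] = []
    errors: list[dict] = []

    def run(cluster: ClusterInput):
        pre = proposals[cluster.cluster_id]
        if isinstance(pre, Exception):
            raise pre
        return _annotate_one(backend, kg, cluster, config, proposals=pre)

    if config.workers <= 1:
        results = []
        for cluster in clusters:
            try:
                results.append((cluster, run(cluster), None))
            except Exception as exc:
                results.append((cluster, None, exc))
    else:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            futures = [(c, pool.submit(run, c)) for c in clusters]
            results = []
            for cluster, fut in futures:
                try:
                    results.append((cluster, fut.result(), None))
                except Exception as exc:
                    results.append((cluster, None, exc))

    for cluster, annotation, exc in results:
        if exc is not None:
            stage = exc.stage if isinstance(exc, StageError) else None
            errors.append(
                {
                    "cluster_id": cluster.cluster_id,
                    "stage": stage,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
        else:
            annotations.append(annotation)

    annotations.sort(key=lambda a: a.cluster_id)
    errors.sort(key=lambda e: e["cluster_id"])
    if not config.explain:
        for a in annotations:
            a.reasoning = None
            a.positive_markers = None
            for comp in a.components or []:
                comp.reasoning = None
                comp.positive_markers = None
    return AnnotationRun(annotations=annotations, errors=errors)
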