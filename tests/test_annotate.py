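"""Three-stage pipeline: mock backend rules, stage contracts, orchestration."""

import itertools
import json

import numpy as np
import pytest

import kganno
from kganno.annotate import (
    AnnotateConfig,
    CandidateProposal,
    ClusterInput,
    MockBackend,
    annotate,
    marker_fingerprint,
    stage1_propose,
    stage2_arbitrate,
    stage3_subtype,
)
from kganno.errors import BackendError, ContractViolationError, StageError
from kganno.retrieve import global_evidence, subgraph_domain


class FlakyBackend:
    """Fault-injection wrapper: returns garbage for the first N calls."""

    def __init__(self, inner, fail_first=1):
        self.inner = inner
        self.remaining_failures = fail_first
        self.calls = 0

    def complete(self, payload, temperature=0.5, seed=None):
        self.calls += 1
        if self.remaining_failures > 0:
            self.remaining_failures -= 1
            return {"unexpected": "garbage"}
        return self.inner.complete(payload, temperature=temperature, seed=seed)


@pytest.fixture
def rulebook():
    return {
        marker_fingerprint(["CD3D", "CD4", "CD8A"]): [
            ["T cell", "TOY:0000002"],
            ["natural killer cell", "TOY:0000008"],
            ["B cell", "TOY:0000005"],
        ]
    }


@pytest.fixture
def cluster():
    return ClusterInput("c1", ["CD3D", "CD4", "CD8A"])


class TestStage1:
    def test_rulebook_lookup_returns_ordered_triple(self, rulebook, cluster):
        proposals = stage1_propose(MockBackend(rulebook), cluster, k=3)
        assert [(p.name, p.rank) for p in proposals] == [
            ("T cell", 1), ("natural killer cell", 2), ("B cell", 3),
        ]

    def test_k_one_returns_single_proposal(self, rulebook, cluster):
        proposals = stage1_propose(MockBackend(rulebook), cluster, k=1)
        assert len(proposals) == 1 and proposals[0].rank == 1

    def test_malformed_response_retried_then_succeeds(self, rulebook, cluster, caplog):
        backend = FlakyBackend(MockBackend(rulebook), fail_first=1)
        with caplog.at_level("WARNING"):
            proposals = stage1_propose(backend, cluster, k=3, retries=2)
        assert len(proposals) == 3
        assert backend.calls == 2
        assert any("parse failure" in r.message for r in caplog.records)

    def test_persistent_failure_raises_stage_error_with_cluster_id(self, rulebook, cluster):
        backend = FlakyBackend(MockBackend(rulebook), fail_first=10)
        with pytest.raises(StageError) as err:
            stage1_propose(backend, cluster, k=3, retries=2)
        assert err.value.cluster_id == "c1"

    def test_unknown_fingerprint_uses_default_or_raises(self, cluster):
        with pytest.raises(BackendError, match="fingerprint"):
            stage1_propose(MockBackend({}), cluster, k=1)
        backend = MockBackend({}, default=[["T cell", "TOY:0000002"]])
        assert stage1_propose(backend, cluster, k=1)[0].name == "T cell"

    def test_marker_dedup_preserves_order(self):
        c = ClusterInput("c9", ["B", "A", "B", " C ", "A"])
        assert c.markers == ["B", "A", "C"]


def _mk_payload(counts, ranks=None, coexpr=None):
    ranks = ranks or list(range(1, len(counts) + 1))
    coexpr = coexpr or [0] * len(counts)
    return {
        "stage": 2,
        "cluster_id": "c",
        "markers": ["M"],
        "mixed_hint": False,
        "candidates": [
            {
                "name": f"cand{i}",
                "ontology_id": f"TOY:000000{i+1}",
                "rank": ranks[i],
                "reasoning": "",
                "pathway_link_count": counts[i],
                "coexpression_support": coexpr[i],
            }
            for i in range(len(counts))
        ],
    }


class TestMockDecisionRules:
    def test_evidence_beats_rank(self):
        resp = MockBackend().complete(_mk_payload([2, 1, 0], ranks=[3, 2, 1]))
        assert resp["name"] == "cand0"  # 2 links wins despite rank 3

    def test_all_tied_evidence_falls_back_to_rank_one(self):
        resp = MockBackend().complete(_mk_payload([1, 1, 1]))
        assert resp["name"] == "cand0"

    def test_identical_payload_gives_identical_response(self):
        payload = _mk_payload([1, 2, 0], coexpr=[3, 0, 1])
        a = MockBackend().complete(payload)
        b = MockBackend().complete(payload)
        assert a == b

    def test_randomized_payloads_match_independent_argmax(self):
        """Dual-implementation check of the stage-2 rule."""
        rng = np.random.default_rng(11)
        backend = MockBackend()
        for _ in range(200):
            n = int(rng.integers(2, 5))
            counts = rng.integers(0, 4, size=n).tolist()
            coexpr = rng.integers(0, 3, size=n).tolist()
            payload = _mk_payload(counts, coexpr=coexpr)
            resp = backend.complete(payload)
            # independent re-implementation: exhaustive pairwise comparison
            best = None
            for c in payload["candidates"]:
                key = (c["pathway_link_count"], c["coexpression_support"], -c["rank"])
                if best is None or key > best[0]:
                    best = (key, c["name"])
            assert resp["name"] == best[1]

    def test_stage3_argmax_chain_then_depth_then_id(self):
        payload = {
            "stage": 3,
            "candidates": [
                {"name": "a", "ontology_id": "TOY:0000009", "chain_count": 1, "depth": 3},
                {"name": "b", "ontology_id": "TOY:0000002", "chain_count": 1, "depth": 3},
                {"name": "c", "ontology_id": "TOY:0000005", "chain_count": 1, "depth": 1},
            ],
        }
        assert MockBackend().complete(payload)["ontology_id"] == "TOY:0000002"
        payload["candidates"][2]["chain_count"] = 5
        assert MockBackend().complete(payload)["ontology_id"] == "TOY:0000005"


class TestStage2:
    def test_candidate_with_more_pathway_links_wins(self, dataset_kg, world, clusters):
        cl = clusters[0]  # T-cell cluster
        backend = MockBackend(world.rulebook)
        proposals = stage1_propose(backend, cl, k=3)
        bundles = global_evidence(dataset_kg, [p.ontology_id for p in proposals],
                                  cl.markers)
        decision = stage2_arbitrate(backend, cl, proposals, bundles, kg=dataset_kg)
        assert decision.name == "T cell"
        assert not decision.is_mixture

    def test_strict_mode_rejects_out_of_candidate_decision(self, dataset_kg, clusters):
        cl = clusters[0]

        class RogueBackend(MockBackend):
            def _stage2(self, payload):
                return {"name": "astrocyte", "ontology_id": "TOY:0009999",
                        "reasoning": "", "is_mixture": False}

        backend = RogueBackend()
        proposals = [
            CandidateProposal("T cell", "TOY:0000002", "", 1),
        ]
        bundles = global_evidence(dataset_kg, ["TOY:0000002"], cl.markers)
        with pytest.raises(ContractViolationError):
            stage2_arbitrate(backend, cl, proposals, bundles, kg=dataset_kg)
        # lenient mode accepts with a warning instead
        decision = stage2_arbitrate(backend, cl, proposals, bundles,
                                    strict=False, kg=dataset_kg)
        assert decision.name == "astrocyte"

    def test_hallucinated_id_with_graph_name_conflict_rejected(self, dataset_kg, clusters):
        """An in-graph id paired with the wrong display name is refused."""
        cl = clusters[0]
        tcell = dataset_kg.resolve_cell_type("T cell")
        bcell = dataset_kg.resolve_cell_type("B cell")

        class HallucinatingBackend(MockBackend):
            def _stage2(self, payload):
                # correct literal name, wrong ontology id
                return {"name": "T cell", "ontology_id": bcell,
                        "reasoning": "", "is_mixture": False}

        proposals = [
            CandidateProposal("T cell", tcell, "", 1),
            CandidateProposal("B cell", bcell, "", 2),
        ]
        bundles = global_evidence(dataset_kg, [tcell, bcell], cl.markers)
        with pytest.raises(ContractViolationError, match="names"):
            stage2_arbitrate(HallucinatingBackend(), cl, proposals, bundles,
                             kg=dataset_kg)

    def test_mixture_detected_when_two_lineages_have_evidence(
        self, dataset_kg, world, clusters
    ):
        mix = next(c for c in clusters if c.cluster_id == "c_mix")
        backend = MockBackend(world.rulebook)
        proposals = stage1_propose(backend, mix, k=3)
        bundles = global_evidence(dataset_kg, [p.ontology_id for p in proposals],
                                  mix.markers)
        decision = stage2_arbitrate(backend, mix, proposals, bundles, kg=dataset_kg)
        assert decision.is_mixture
        got = sorted(term for _, term in decision.components)
        truth = next(c for c in world.clusters if c["cluster_id"] == "c_mix")
        assert got == truth["components"]


class TestStage3:
    def test_single_candidate_subtype_returned(self, dataset_kg, world, clusters):
        cl = clusters[0]
        backend = MockBackend(world.rulebook)
        decision = kganno.MajorDecision(cl.cluster_id, "T cell",
                                        dataset_kg.resolve_cell_type("T cell"), "")
        sub = subgraph_domain(dataset_kg, decision.ontology_id, cl.markers)
        ann = stage3_subtype(backend, cl, decision, sub, dataset_kg)
        assert ann.name == "CD4-positive T cell"
        assert ann.positive_markers  # evidence genes recorded

    def test_empty_domain_falls_back_to_major(self, dataset_kg, world, clusters):
        cl = clusters[0]  # T-cell markers carry no chains into the B lineage
        backend = MockBackend(world.rulebook)
        bid = dataset_kg.resolve_cell_type("B cell")
        decision = kganno.MajorDecision(cl.cluster_id, "B cell", bid, "")
        sub = subgraph_domain(dataset_kg, bid, cl.markers)
        assert not sub.candidate_subtypes
        ann = stage3_subtype(backend, cl, decision, sub, dataset_kg)
        assert ann.ontology_id == bid
        assert ann.name == "B cell"

    def test_child_with_two_chains_beats_sibling_with_one(self):
        from kganno.graph import (
            HAS_ACTIVITY_IN, IS_A, PARTICIPATES_IN, CellTypeNode,
            KnowledgeGraph, PathwayNode,
        )

        kg = KnowledgeGraph()
        kg.add_cell_type(CellTypeNode("TOY:0000001", "cell"))
        kg.add_cell_type(CellTypeNode("TOY:0000002", "macrophage"))
        kg.add_cell_type(CellTypeNode("TOY:0000003", "microglial cell"))
        kg.add_cell_type(CellTypeNode("TOY:0000004", "alveolar macrophage"))
        kg.add_edge("TOY:0000002", "TOY:0000001", IS_A)
        kg.add_edge("TOY:0000003", "TOY:0000002", IS_A)
        kg.add_edge("TOY:0000004", "TOY:0000002", IS_A)
        for g, pw, target in (
            ("SPP1", "P1", "TOY:0000003"),
            ("APBB1IP", "P2", "TOY:0000003"),
            ("MARCO", "P3", "TOY:0000004"),
        ):
            kg.add_gene(g)
            kg.add_pathway(PathwayNode(pw, pw, {g}))
            kg.add_edge(g, pw, PARTICIPATES_IN)
            kg.add_edge(pw, target, HAS_ACTIVITY_IN)
        cl = ClusterInput("c1", ["SPP1", "APBB1IP", "MARCO"])
        decision = kganno.MajorDecision("c1", "macrophage", "TOY:0000002", "")
        sub = subgraph_domain(kg, "TOY:0000002", cl.markers)
        ann = stage3_subtype(MockBackend(), cl, decision, sub, kg)
        assert ann.name == "microglial cell"
        assert sorted(ann.positive_markers) == ["APBB1IP", "SPP1"]

    def test_stage3_prompt_contains_only_domain_cell_types(
        self, dataset_kg, world, clusters
    ):
        """Token budget: the focused prompt must not leak out-of-domain types."""
        cl = clusters[0]
        tid = dataset_kg.resolve_cell_type("T cell")
        sub = subgraph_domain(dataset_kg, tid, cl.markers)
        captured = {}

        class CapturingBackend(MockBackend):
            def complete(self, payload, temperature=0.5, seed=None):
                captured.update(payload)
                return super().complete(payload, temperature=temperature, seed=seed)

        decision = kganno.MajorDecision(cl.cluster_id, "T cell", tid, "")
        stage3_subtype(CapturingBackend(), cl, decision, sub, dataset_kg)
        prompt = captured["prompt"]
        domain_names = {dataset_kg.cell_types[t].name for t in sub.domain}
        for term_id, node in dataset_kg.cell_types.items():
            if node.name in domain_names:
                continue
            if any(node.name in dn for dn in domain_names):
                continue  # e.g. the root "cell" is a substring of "T cell"
            assert node.name not in prompt
            assert term_id not in prompt


class TestAnnotateOrchestration:
    def test_output_identical_across_runs_and_worker_counts(
        self, dataset_kg, world, clusters
    ):
        outputs = []
        for workers in (1, 4, 64):
            run = annotate(
                MockBackend(world.rulebook), dataset_kg, clusters,
                AnnotateConfig(workers=workers),
            )
            assert run.errors == []
            outputs.append(run.to_jsonl())
        assert outputs[0] == outputs[1] == outputs[2]
        rerun = annotate(MockBackend(world.rulebook), dataset_kg, clusters,
                         AnnotateConfig(workers=4))
        assert rerun.to_jsonl() == outputs[0]

    def test_explain_false_strips_reasoning_and_evidence(
        self, dataset_kg, world, clusters
    ):
        on = annotate(MockBackend(world.rulebook), dataset_kg, clusters,
                      AnnotateConfig(explain=True))
        off = annotate(MockBackend(world.rulebook), dataset_kg, clusters,
                       AnnotateConfig(explain=False))
        for rec in (json.loads(l) for l in off.to_jsonl(explain=False).splitlines()):
            assert "reasoning" not in rec
            assert "positive_markers" not in rec
        labels_on = [(a.cluster_id, a.ontology_id) for a in on.annotations]
        labels_off = [(a.cluster_id, a.ontology_id) for a in off.annotations]
        assert labels_on == labels_off

    def test_failed_cluster_isolated_in_error_manifest(
        self, dataset_kg, world, clusters
    ):
        broken = dict(world.rulebook)
        removed_fp = marker_fingerprint(clusters[2].markers)
        del broken[removed_fp]
        run = annotate(MockBackend(broken), dataset_kg, clusters,
                       AnnotateConfig(workers=2))
        assert len(run.errors) == 1
        assert run.errors[0]["cluster_id"] == clusters[2].cluster_id
        assert len(run.annotations) == len(clusters) - 1

    def test_batched_and_unbatched_stage1_agree(self, dataset_kg, world, clusters):
        batched = annotate(MockBackend(world.rulebook), dataset_kg, clusters,
                           AnnotateConfig(batch_size=4))
        single = annotate(MockBackend(world.rulebook), dataset_kg, clusters,
                          AnnotateConfig(batch_size=1))
        assert batched.to_jsonl() == single.to_jsonl()

    def test_emitted_ids_resolve_and_names_match_graph(
        self, dataset_kg, world, clusters
    ):
        run = annotate(MockBackend(world.rulebook), dataset_kg, clusters,
                       AnnotateConfig())
        for a in run.annotations:
            node = dataset_kg.cell_types[a.ontology_id]
            assert node.name == a.name
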