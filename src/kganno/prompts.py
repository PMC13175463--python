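"""Versioned prompt templates for the three annotation stages.

The templates demand structured JSON replies so responses are parseable and
testable.  Stage 2 ships in three arbitration styles:

* ``neutral`` (default) — graph evidence is a reference, weighed critically;
* ``kg_biased`` — the decision must be based on the graph evidence;
* ``llm_biased`` — the model is told to trust its own judgment over the
  evidence.

The biased styles exist to study how anchoring the arbiter on either source
degrades accuracy; neutral wording is the recommended setting.
"""

from __future__ import annotations

PROMPT_VERSION = "1.0"

STAGE1_TEMPLATE = """\
You are an expert in single-cell transcriptomics. Your task is to act as a
primary annotator. For each provided cell cluster index and its marker genes,
you must propose the {k} most probable broad cell lineages (major types).
Your reasoning should be based on your deep biological knowledge. The
candidates should be ordered from most likely to least likely.
{mixture_instruction}
Cluster {cluster_id} markers: {markers}

Reply with JSON: {{"candidates": [{{"name": ..., "ontology_id": ...,
"reasoning": ..., "rank": 1..{k}}}]}}
"""

MIXTURE_INSTRUCTION = (
    "Please be aware that the provided markers for each index may represent "
    "a combination of two distinct cell types."
)

_STAGE2_STANCE = {
    "neutral": (
        "The Knowledge Graph contains curated, symbolic knowledge about cell "
        "types. Your decision should consider the provided KG summaries for "
        "each candidate, treating them as a reference rather than absolute "
        "truth, and weigh them critically against your own expertise."
    ),
    "kg_biased": (
        "Your decision must be based on the evidence from the knowledge "
        "graph."
    ),
    "llm_biased": (
        "The KG summaries are provided for context, but trust your expert "
        "judgment to resolve any discrepancies or conflicts."
    ),
}

STAGE2_TEMPLATE = """\
You are a senior computational biologist acting as the final arbiter for a
challenging cell type annotation case. An initial analysis has yielded
several hypotheses. Your task is to critically evaluate all available
qualitative evidence from the Knowledge Graph to make a definitive judgment
on the most likely major cell type. {stance}

Cluster {cluster_id} markers: {markers}

Candidates and their reasoning:
{candidates}

Knowledge-graph evidence:
{evidence}

Reply with JSON: {{"name": ..., "ontology_id": ..., "reasoning": ...,
"is_mixture": false}} or, when the markers clearly combine two lineages,
{{"is_mixture": true, "components": [{{"name": ..., "ontology_id": ...}},
{{"name": ..., "ontology_id": ...}}], "reasoning": ...}}
"""

STAGE3_TEMPLATE = """\
You are a cell annotation specialist. The major cell type has been
confidently identified. Your task is to determine the most specific subtype
based on the provided focused evidence from a knowledge graph.

Cluster {cluster_id} markers: {markers}
{background_note}
Confirmed major type: {major_name} [{major_id}]

Focused subgraph evidence:
{evidence}

Reply with JSON: {{"name": ..., "ontology_id": ..., "reasoning": ...,
"positive_markers": [...]}}
"""


def render_stage1(cluster_id, markers, k: int, mixed_hint: bool) -> str:
    return STAGE1_TEMPLATE.format(
        cluster_id=cluster_id,
        markers=", ".join(markers),
        k=k,
        mixture_instruction=MIXTURE_INSTRUCTION + "\n" if mixed_hint else "",
    )


def render_stage2(cluster_id, markers, candidates_block: str, evidence_block: str,
                  style: str = "neutral") -> str:
    if style not in _STAGE2_STANCE:
        raise ValueError(f"unknown prompt style {style!r}; "
                         f"expected one of {sorted(_STAGE2_STANCE)}")
    return STAGE2_TEMPLATE.format(
        cluster_id=cluster_id,
        markers=", ".join(markers),
        candidates=candidates_block,
        evidence=evidence_block,
        stance=_STAGE2_STANCE[style],
    )


def render_stage3(cluster_id, markers, major_name, major_id, evidence_block: str,
                  background_markers: list[str] | None = None) -> str:
    note = ""
    if background_markers:
        note = (
            "Treat these markers as background noise from a co-occurring "
            f"population: {', '.join(background_markers)}\n"
        )
    return STAGE3_TEMPLATE.format(
        cluster_id=cluster_id,
        markers=", ".join(markers),
        background_note=note,
        major_name=major_name,
        major_id=major_id,
        evidence=evidence_block,
    )
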