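"""Ontology-aware agreement scoring and cross-dataset comparison statistics.

Predictions are compared with ground-truth labels hierarchically rather than
flatly: an exact term (or ontology synonym) scores 1.0, a near miss — sibling
terms sharing a direct parent, or a direct parent–child pair — scores 0.5,
and everything else scores 0.0.  The 0/0.5 split penalises a one-level
generalisation or a sibling confusion less than a wrong lineage altogether.
A dataset's agreement score is the arithmetic mean over its clusters.

"Major lineages" for mismatch reporting are a configurable set of terms
(default: the direct children of the ontology root); every term resolves to
its nearest ancestor in that set, itself included.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import KgannoError, UnknownTermError, AmbiguousTermError
from .graph import KnowledgeGraph

log = logging.getLogger(__name__)

FULLY = "fully"
PARTIALLY = "partially"
MISMATCH = "mismatch"
_CLASS_SCORE = {FULLY: 1.0, PARTIALLY: 0.5, MISMATCH: 0.0}


@dataclass(frozen=True)
class AgreementVerdict:
    cluster_id: str
    truth: tuple[str, str]  # (name, id)
    prediction: tuple[str, str]
    match_class: str
    score: float
    reason: str = ""

    def __post_init__(self) -> None:
        if self.score != _CLASS_SCORE[self.match_class]:
            raise KgannoError(
                f"score {self.score} inconsistent with class {self.match_class!r}"
            )


@dataclass
class ScoreReport:
    dataset_id: str
    verdicts: list[AgreementVerdict]
    mean_score: float
    class_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "n_clusters": len(self.verdicts),
            "mean_score": self.mean_score,
            "class_counts": self.class_counts,
        }


def default_major_lineages(kg: KnowledgeGraph) -> set[str]:
    """Direct children of the ontology root(s): the default lineage partition."""
    lineages: set[str] = set()
    for root in kg.roots():
        lineages.update(kg.children(root))
    return lineages


def resolve_lineage(kg: KnowledgeGraph, term_id: str, lineages: set[str]) -> str | None:
    """Nearest ancestor of ``term_id`` (inclusive) within the lineage set."""
    frontier = [term_id]
    seen = set(frontier)
    while frontier:
        nxt: list[str] = []
        hits = sorted(t for t in frontier if t in lineages)
        if hits:
            return hits[0]
        for t in frontier:
            for parent in kg.parents(t):
                if parent not in seen:
                    seen.add(parent)
                    nxt.append(parent)
        frontier = nxt
    return None


def classify_match(
    kg: KnowledgeGraph,
    truth: str,
    prediction: str,
    cluster_id: str = "",
    major_lineages: set[str] | None = None,
    distant_same_lineage_partial: bool = False,
) -> AgreementVerdict:
    """Classify one prediction against the ground truth.

    Precedence is fully > partially > mismatch.  ``truth`` must resolve in
    the ontology; an unresolvable ``prediction`` (e.g. a hallucinated label)
    is a mismatch, not an error, so evaluation never aborts.  With
    ``distant_same_lineage_partial`` a same-lineage relation more distant
    than one level also scores 0.5 instead of 0.0.
    """
    truth_id = kg.resolve_cell_type(truth)  # raises if unresolvable
    truth_node = kg.cell_types[truth_id]
    try:
        pred_id = kg.resolve_cell_type(prediction)
    except (UnknownTermError, AmbiguousTermError) as exc:
        log.info("prediction %r not resolvable: %s", prediction, exc)
        return AgreementVerdict(
            cluster_id=str(cluster_id),
            truth=(truth_node.name, truth_id),
            prediction=(prediction, ""),
            match_class=MISMATCH,
            score=0.0,
            reason="prediction not resolvable in the ontology",
        )
    pred_node = kg.cell_types[pred_id]

    def verdict(match_class: str, reason: str) -> AgreementVerdict:
        return AgreementVerdict(
            cluster_id=str(cluster_id),
            truth=(truth_node.name, truth_id),
            prediction=(pred_node.name, pred_id),
            match_class=match_class,
            score=_CLASS_SCORE[match_class],
            reason=reason,
        )

    if pred_id == truth_id:
        return verdict(FULLY, "identical term (or exact synonym)")

    truth_parents = set(kg.parents(truth_id))
    pred_parents = set(kg.parents(pred_id))
    if truth_parents & pred_parents:
        return verdict(PARTIALLY, "sibling terms sharing a direct parent")
    if pred_id in truth_parents or truth_id in pred_parents:
        return verdict(PARTIALLY, "direct parent-child relation")

    lineages = major_lineages if major_lineages is not None else default_major_lineages(kg)
    truth_lineage = resolve_lineage(kg, truth_id, lineages)
    pred_lineage = resolve_lineage(kg, pred_id, lineages)
    if (
        distant_same_lineage_partial
        and truth_lineage is not None
        and truth_lineage == pred_lineage
    ):
        return verdict(PARTIALLY, "same major lineage (distant relation)")
    if truth_lineage is not None and truth_lineage == pred_lineage:
        return verdict(MISMATCH, "same major lineage but no direct relation")
    return verdict(MISMATCH, "different major lineages")


def dataset_score(
    verdicts: Sequence[AgreementVerdict], dataset_id: str = "dataset"
) -> ScoreReport:
    """Arithmetic mean of per-cluster agreement scores."""
    if not verdicts:
        raise KgannoError("cannot score an empty verdict list")
    counts = {FULLY: 0, PARTIALLY: 0, MISMATCH: 0}
    for v in verdicts:
        counts[v.match_class] += 1
    return ScoreReport(
        dataset_id=dataset_id,
        verdicts=list(verdicts),
        mean_score=float(np.mean([v.score for v in verdicts])),
        class_counts=counts,
    )


@dataclass(frozen=True)
class PairedComparison:
    mean_diff: float
    cohens_d: float | None  # None when the differences have zero variance
    p_value: float | None

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "cohens_d": self.cohens_d,
            "p_value": self.p_value,
        }


def paired_comparison(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> PairedComparison:
    """Paired cross-dataset comparison of two methods' per-dataset means.

    Returns the mean difference, the paired-differences Cohen's d
    (``d_z = mean(a - b) / sd(a - b)`` with the sample standard deviation)
    and a two-sided paired t-test p-value.  With zero-variance differences d
    is undefined and p is omitted.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise KgannoError("score vectors must be 1-D and paired by dataset")
    if a.size < 2:
        raise KgannoError("need at least 2 paired datasets")
    diff = a - b
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    # constant differences (up to float rounding) leave d undefined
    if math.isnan(sd) or sd <= 1e-9 * max(1.0, abs(mean_diff)):
        return PairedComparison(mean_diff=mean_diff, cohens_d=None, p_value=None)
    d = mean_diff / sd
    t = stats.ttest_rel(a, b)
    return PairedComparison(mean_diff=mean_diff, cohens_d=float(d),
                            p_value=float(t.pvalue))
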