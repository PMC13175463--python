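"""Dataset-specific edge inference.

Two relation types are statistically inferred from a labelled expression
matrix and attached to the base knowledge graph:

* ``COEXPRESSED_IN`` — for every cell-type label, every unordered gene pair
  is tested with the Pearson product-moment correlation

  .. math:: r = \\frac{\\sum_i (x_i - \\bar x)(y_i - \\bar y)}
                     {\\sqrt{\\sum_i (x_i-\\bar x)^2}\\sqrt{\\sum_i (y_i-\\bar y)^2}}

  over the label's cells; an edge is kept iff ``|r| > r_threshold`` *and*
  the Benjamini–Hochberg adjusted p-value is below ``fdr_threshold``.
  p-values come from the usual two-sided t-test with ``n - 2`` degrees of
  freedom and the BH family is the set of testable pairs within one label.

* ``HAS_ACTIVITY_IN`` — per-cell pathway activity is the area under the
  recovery curve (AUCell): genes in a cell are ranked by expression, the
  recovery fraction ``f(k) = |{g in S : rank(g) <= k}| / |S|`` is summed
  over ranks ``1..T`` (``T`` defaults to the top 5% of genes) and divided
  by the maximum attainable area so scores live in ``[0, 1]``.  A pathway
  gains an edge into a cell type when a one-sided Wilcoxon rank-sum test
  (target label vs all remaining cells, BH-corrected across every
  pathway×label pair) is significant and the target median exceeds the
  rest median.

Ranking ties are broken by descending expression then ascending gene
symbol, which makes every score reproducible without a random seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ConstantVectorError, ParameterError
from .graph import COEXPRESSED_IN, HAS_ACTIVITY_IN, KnowledgeGraph

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log-normalized cells × genes expression with per-cell labels."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("expression values must be a 2-D cells × genes array")
        n_cells, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ParameterError("gene_ids length does not match matrix columns")
        if len(self.cell_ids) != n_cells or len(self.labels) != n_cells:
            raise ParameterError("cell_ids/labels length does not match matrix rows")
        if len(set(self.gene_ids)) != n_genes:
            raise ParameterError("gene_ids must be unique")
        if np.any(self.values < 0):
            raise ParameterError("log-normalized expression cannot be negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def cells_with_label(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == label)

    def label_counts(self) -> dict[str, int]:
        unique, counts = np.unique(np.asarray(self.labels), return_counts=True)
        return dict(zip(unique.tolist(), counts.tolist()))


@dataclass(frozen=True)
class CoexpressionResult:
    gene_x: str
    gene_y: str
    r: float
    p: float
    fdr: float
    context: str

    def __post_init__(self) -> None:
        if self.gene_x > self.gene_y:  # canonical unordered pair
            gx, gy = self.gene_y, self.gene_x
            object.__setattr__(self, "gene_x", gx)
            object.__setattr__(self, "gene_y", gy)


@dataclass
class GeneRanking:
    """Per-cell ranking of all genes, rank 1 = highest expression."""

    cell_id: str
    ranks: dict[str, int]

    def __post_init__(self) -> None:
        positions = sorted(self.ranks.values())
        if positions != list(range(1, len(self.ranks) + 1)):
            raise ParameterError("ranks must be a permutation of 1..G")


@dataclass
class ActivityScore:
    pathway_id: str | None
    cell_id: str | None
    auc: float
    threshold_T: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0 + 1e-12:
            raise ParameterError(f"AUC {self.auc} outside [0, 1]")
        if self.threshold_T < 1:
            raise ParameterError("rank threshold T must be >= 1")


@dataclass(frozen=True)
class ActivityEdge:
    pathway_id: str
    cell_type: str
    p_adj: float
    median_gap: float


@dataclass
class KGBuildConfig:
    """Thresholds for dataset edge inference."""

    r_threshold: float = 0.8
    fdr_threshold: float = 0.05
    activity_alpha: float = 0.05
    aucell_top_fraction: float = 0.05
    target_sum: float = 10_000.0
    normalize_auc: bool = True
    seed: int = 0


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def log_normalize(
    counts: np.ndarray,
    gene_ids: Sequence[str],
    cell_ids: Sequence[str],
    labels: Sequence[str],
    target_sum: float = 10_000.0,
) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then apply log1p."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ParameterError("counts must be non-negative")
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [cell_ids[i] for i in zero[:5]]
        raise ParameterError(f"cells with zero total counts: {names}")
    values = np.log1p(counts / totals[:, None] * target_sum)
    return ExpressionMatrix(values, list(gene_ids), list(cell_ids), list(labels))


# ---------------------------------------------------------------------------
# co-expression
# ---------------------------------------------------------------------------

def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided p-value (t-test, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def coexpression_edges(
    expr: ExpressionMatrix,
    r_threshold: float = 0.8,
    fdr_threshold: float = 0.05,
) -> list[CoexpressionResult]:
    """Per-label all-pairs correlation screen with a joint |r| + FDR gate.

    The BH adjustment is applied within each label's family of testable
    pairs; constant genes within a label are skipped with a logged reason.
    """
    results: list[CoexpressionResult] = []
    labels = np.asarray(expr.labels)
    any_label_ok = False
    for label in sorted(set(expr.labels)):
        idx = np.flatnonzero(labels == label)
        n = idx.size
        if n < 3:
            warnings.warn(
                f"label {label!r} has {n} < 3 cells; skipped for co-expression"
            )
            continue
        any_label_ok = True
        sub = expr.values[idx]
        variable = np.flatnonzero(np.ptp(sub, axis=0) > 0)
        dropped = expr.n_genes - variable.size
        if dropped:
            log.info("label %s: %d constant genes excluded from pairs", label, dropped)
        if variable.size < 2:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(sub[:, variable], rowvar=False)
        iu, ju = np.triu_indices(variable.size, k=1)
        r = np.clip(corr[iu, ju], -1.0, 1.0)
        # two-sided t-test with n-2 df
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.minimum(p, 1.0)
        _, fdr, _, _ = multipletests(p, method="fdr_bh")
        keep = (np.abs(r) > r_threshold) & (fdr < fdr_threshold)
        for k in np.flatnonzero(keep):
            gx = expr.gene_ids[variable[iu[k]]]
            gy = expr.gene_ids[variable[ju[k]]]
            results.append(
                CoexpressionResult(
                    gene_x=min(gx, gy),
                    gene_y=max(gx, gy),
                    r=float(r[k]),
                    p=float(p[k]),
                    fdr=float(fdr[k]),
                    context=label,
                )
            )
    if not any_label_ok:
        raise ConfigurationError("no label has >= 3 cells; cannot test co-expression")
    results.sort(key=lambda c: (c.context, c.gene_x, c.gene_y))
    return results


# ---------------------------------------------------------------------------
# AUCell
# ---------------------------------------------------------------------------

def rank_genes(
    expr_row: Sequence[float], gene_ids: Sequence[str], cell_id: str = ""
) -> GeneRanking:
    """Rank one cell's genes from high to low expression.

    Ties are broken by ascending gene symbol so rankings are deterministic.
    An all-zero cell degenerates to pure symbol order (warned).
    """
    values = np.asarray(expr_row, dtype=float)
    if values.ndim != 1 or values.size != len(gene_ids):
        raise ParameterError("expr_row must cover the full gene universe")
    if np.ptp(values) == 0:
        warnings.warn(f"cell {cell_id!r} is constant; ranking is tie-break order only")
    order = sorted(range(values.size), key=lambda i: (-values[i], gene_ids[i]))
    ranks = {gene_ids[i]: pos + 1 for pos, i in enumerate(order)}
    return GeneRanking(cell_id=cell_id, ranks=ranks)


def recovery_fraction(k: int, gene_set: Iterable[str], ranking: GeneRanking) -> float:
    """Fraction of the gene set found among the top-k ranked genes."""
    members = set(gene_set)
    if not members:
        raise ParameterError("gene set is empty")
    G = len(ranking.ranks)
    if not 0 <= k <= G:
        raise ParameterError(f"k={k} outside [0, {G}]")
    unknown = members - set(ranking.ranks)
    if unknown:
        raise ParameterError(f"gene set members outside the universe: {sorted(unknown)}")
    hit = sum(1 for g in members if ranking.ranks[g] <= k)
    return hit / len(members)


def default_rank_threshold(n_genes: int, top_fraction: float = 0.05) -> int:
    """Rank cutoff T: the top ``top_fraction`` of the gene universe."""
    if not 0 < top_fraction <= 1:
        raise ParameterError("top_fraction must be in (0, 1]")
    return max(1, math.ceil(top_fraction * n_genes))


def max_recovery_area(set_size: int, T: int) -> float:
    """Maximum attainable sum of the recovery fraction over ranks 1..T."""
    m = min(set_size, T)
    return (m * (m + 1) / 2) / set_size + max(0, T - set_size)


def aucell_score(
    gene_set: Iterable[str],
    ranking: GeneRanking,
    T: int | None = None,
    normalize: bool = True,
    pathway_id: str | None = None,
) -> ActivityScore:
    """Discrete area under the recovery curve for one cell.

    The raw area is ``sum_{k=1..T} f(k)``; with ``normalize=True`` (default)
    it is divided by the maximum attainable area for ``(|S|, T)`` so a
    perfect recovery scores 1.0.
    """
    members = set(gene_set)
    if not members:
        raise ParameterError("gene set is empty")
    G = len(ranking.ranks)
    if T is None:
        T = default_rank_threshold(G)
    if T < 1 or T > G:
        raise ParameterError(f"T={T} outside [1, {G}]")
    # a member at rank r <= T contributes (T - r + 1)/|S| to the area
    raw = sum(
        (T - ranking.ranks[g] + 1) for g in members if ranking.ranks[g] <= T
    ) / len(members)
    if normalize:
        raw /= max_recovery_area(len(members), T)
    return ActivityScore(
        pathway_id=pathway_id, cell_id=ranking.cell_id, auc=float(raw), threshold_T=T
    )


def _rank_matrix(expr: ExpressionMatrix) -> np.ndarray:
    """cells × genes matrix of ranks (1 = highest), symbol-order tie-break."""
    symbol_order = np.argsort(np.asarray(expr.gene_ids))
    sorted_vals = expr.values[:, symbol_order]
    # stable sort on descending value: ties keep ascending-symbol order
    order = np.argsort(-sorted_vals, axis=1, kind="stable")
    ranks_sorted = np.empty_like(order)
    rows = np.arange(expr.n_cells)[:, None]
    ranks_sorted[rows, order] = np.arange(1, expr.n_genes + 1)[None, :]
    ranks = np.empty_like(ranks_sorted)
    ranks[:, symbol_order] = ranks_sorted
    return ranks


def aucell_matrix(
    expr: ExpressionMatrix,
    gene_sets: Mapping[str, Iterable[str]],
    top_fraction: float = 0.05,
    normalize: bool = True,
) -> pd.DataFrame:
    """AUCell scores for every (cell, pathway); cells × pathways frame.

    Pathway members absent from the expression gene universe are dropped;
    pathways with no present member are skipped with a warning.
    """
    T = default_rank_threshold(expr.n_genes, top_fraction)
    ranks = _rank_matrix(expr)
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    columns: dict[str, np.ndarray] = {}
    for pw_id in sorted(gene_sets):
        members = [g for g in set(gene_sets[pw_id]) if g in gene_index]
        if not members:
            warnings.warn(f"pathway {pw_id!r} has no member in the expression matrix")
            continue
        member_ranks = ranks[:, [gene_index[g] for g in members]]
        contrib = np.clip(T - member_ranks + 1, 0, None)
        raw = contrib.sum(axis=1) / len(members)
        if normalize:
            raw = raw / max_recovery_area(len(members), T)
        columns[pw_id] = raw
    frame = pd.DataFrame(columns, index=list(expr.cell_ids))
    frame.attrs["threshold_T"] = T
    return frame


# ---------------------------------------------------------------------------
# activity edges
# ---------------------------------------------------------------------------

def activity_edges(
    scores: pd.DataFrame,
    labels: Sequence[str],
    alpha: float = 0.05,
) -> list[ActivityEdge]:
    """One-vs-rest Wilcoxon rank-sum screen over (pathway, cell type) pairs.

    For every pathway and label, target-label scores are compared against
    all remaining cells with a one-sided (greater) rank-sum test; BH
    correction runs across the full family of pairs and an edge requires
    both an adjusted p below ``alpha`` and a strictly higher target median.
    """
    labels = np.asarray(list(labels))
    if len(labels) != scores.shape[0]:
        raise ParameterError("labels length must match score rows")
    unique = sorted(set(labels.tolist()))
    if len(unique) < 2:
        raise ParameterError("need >= 2 distinct labels for one-vs-rest tests")
    counts = {u: int((labels == u).sum()) for u in unique}
    small = [u for u, c in counts.items() if c < 2]
    if small:
        raise ParameterError(f"labels with < 2 cells: {small}")

    records: list[tuple[str, str, float, float]] = []
    for pw_id in scores.columns:
        col = scores[pw_id].to_numpy()
        for label in unique:
            mask = labels == label
            target, rest = col[mask], col[~mask]
            gap = float(np.median(target) - np.median(rest))
            if np.ptp(col) == 0:
                p = 1.0  # all scores identical: no evidence either way
            else:
                p = float(
                    stats.mannwhitneyu(target, rest, alternative="greater").pvalue
                )
            records.append((pw_id, label, p, gap))
    if not records:
        return []
    pvals = np.array([rec[2] for rec in records])
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    edges = [
        ActivityEdge(pathway_id=pw, cell_type=label, p_adj=float(pa), median_gap=gap)
        for (pw, label, _, gap), pa in zip(records, p_adj)
        if pa < alpha and gap > 0
    ]
    edges.sort(key=lambda e: (e.pathway_id, e.cell_type))
    return edges


# ---------------------------------------------------------------------------
# graph assembly
# ---------------------------------------------------------------------------

def build_dataset_kg(
    base: KnowledgeGraph,
    expr: ExpressionMatrix,
    config: KGBuildConfig | None = None,
) -> KnowledgeGraph:
    """Attach dataset-inferred co-expression and activity edges to a copy of
    the base graph.  The base graph is never mutated."""
    config = config or KGBuildConfig()
    kg = base.copy()

    overlap = set(expr.gene_ids) & set(kg.genes)
    if not overlap:
        raise ConfigurationError(
            "expression matrix shares no gene symbols with the base graph"
        )
    label_map: dict[str, str] = {}
    for label in sorted(set(expr.labels)):
        try:
            label_map[label] = kg.resolve_cell_type(label)
        except Exception:
            warnings.warn(f"label {label!r} does not resolve to an ontology term")
    if not label_map:
        raise ConfigurationError("no expression label maps to a cell-type node")

    for co in coexpression_edges(expr, config.r_threshold, config.fdr_threshold):
        if co.context not in label_map:
            continue
        if co.gene_x not in kg.genes or co.gene_y not in kg.genes:
            continue
        kg.add_edge(
            co.gene_x,
            co.gene_y,
            COEXPRESSED_IN,
            {
                "r": round(co.r, 6),
                "fdr": round(co.fdr, 10),
                "context": label_map[co.context],
            },
        )

    gene_sets = {pw.id: pw.members for pw in kg.pathways.values()}
    scores = aucell_matrix(
        expr, gene_sets, config.aucell_top_fraction, config.normalize_auc
    )
    mapped = [lbl for lbl in expr.labels]
    if not scores.empty and len(set(mapped)) >= 2:
        for edge in activity_edges(scores, mapped, config.activity_alpha):
            if edge.cell_type not in label_map:
                continue
            kg.add_edge(
                edge.pathway_id,
                label_map[edge.cell_type],
                HAS_ACTIVITY_IN,
                {"p_adj": round(edge.p_adj, 10), "median_gap": round(edge.median_gap, 6)},
            )

    kg.provenance["dataset_edges"] = {
        "r_threshold": config.r_threshold,
        "fdr_threshold": config.fdr_threshold,
        "activity_alpha": config.activity_alpha,
        "aucell_top_fraction": config.aucell_top_fraction,
        "target_sum": config.target_sum,
        "normalize_auc": config.normalize_auc,
        "seed": config.seed,
        "n_cells": expr.n_cells,
        "n_genes": expr.n_genes,
    }
    return kg
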