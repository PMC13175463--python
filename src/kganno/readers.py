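"""Readers for the tabular inputs: expression matrices, marker lists,
truth labels and mock-backend rulebooks."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import ClusterInput
from .construct import ExpressionMatrix, log_normalize
from .errors import ConfigurationError


def read_expression_csv(
    path: str | Path, target_sum: float = 10_000.0, normalize: bool = True
) -> ExpressionMatrix:
    """Dense CSV with ``cell_id`` and ``cell_type`` columns plus gene columns."""
    frame = pd.read_csv(path)
    for col in ("cell_id", "cell_type"):
        if col not in frame.columns:
            raise ConfigurationError(f"{path}: missing required column {col!r}")
    gene_cols = [c for c in frame.columns if c not in ("cell_id", "cell_type")]
    counts = frame[gene_cols].to_numpy(dtype=float)
    cell_ids = frame["cell_id"].astype(str).tolist()
    labels = frame["cell_type"].astype(str).tolist()
    if normalize:
        return log_normalize(counts, gene_cols, cell_ids, labels, target_sum)
    return ExpressionMatrix(counts, gene_cols, cell_ids, labels)


def read_expression_mtx(
    mtx_dir: str | Path, target_sum: float = 10_000.0, normalize: bool = True
) -> ExpressionMatrix:
    """Matrix Market directory: ``matrix.mtx`` (cells × genes) with
    ``genes.tsv`` and ``cells.tsv`` (cell id TAB cell type) sidecars."""
    from scipy.io import mmread

    mtx_dir = Path(mtx_dir)
    counts = np.asarray(mmread(mtx_dir / "matrix.mtx").todense(), dtype=float)
    genes = (mtx_dir / "genes.tsv").read_text().split()
    cells, labels = [], []
    for line in (mtx_dir / "cells.tsv").read_text().splitlines():
        cid, label = line.split("\t")
        cells.append(cid)
        labels.append(label)
    if normalize:
        return log_normalize(counts, genes, cells, labels, target_sum)
    return ExpressionMatrix(counts, genes, cells, labels)


def read_markers(path: str | Path, mixed_hint: bool = False) -> list[ClusterInput]:
    """Markers CSV (``cluster_id,marker_1..marker_n``) or JSON
    (``{cluster_id: [genes]}``)."""
    path = Path(path)
    clusters: list[ClusterInput] = []
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        for cid in sorted(data):
            clusters.append(ClusterInput(str(cid), list(data[cid]), mixed_hint))
        return clusters
    frame = pd.read_csv(path, dtype=str)
    if "cluster_id" not in frame.columns:
        raise ConfigurationError(f"{path}: missing required column 'cluster_id'")
    marker_cols = [c for c in frame.columns if c != "cluster_id"]
    for _, row in frame.iterrows():
        markers = [row[c] for c in marker_cols if isinstance(row[c], str) and row[c]]
        clusters.append(ClusterInput(str(row["cluster_id"]), markers, mixed_hint))
    return clusters


def read_truth(path: str | Path) -> dict[str, tuple[str, str]]:
    """Truth CSV ``cluster_id,true_name,true_id`` -> {id: (name, term id)}."""
    frame = pd.read_csv(path, dtype=str)
    for col in ("cluster_id", "true_name", "true_id"):
        if col not in frame.columns:
            raise ConfigurationError(f"{path}: missing required column {col!r}")
    return {
        str(r["cluster_id"]): (str(r["true_name"]), str(r["true_id"]))
        for _, r in frame.iterrows()
    }


def read_rulebook(path: str | Path) -> dict[str, list]:
    data = json.loads(Path(path).read_text())
    return {k: [list(p) for p in v] for k, v in data.items()}


def read_annotations_jsonl(path: str | Path) -> list[dict]:
    records = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            records.append(json.loads(line))
    return records
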