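"""Dataset integration: one global gene-interaction network, one
expression-score table.

Interaction datasets are merged by edge union.  Every edge carries the
average interaction weight over the datasets reporting it (an unweighted
dataset contributes weight 1.0 — the "certain interaction" reading, the
only convention under which the merged weight range can reach 1 when
edges are reported solely by unweighted sources) and the *dataset
coverage*, the fraction of integrated datasets reporting the edge.

Expression datasets are normalized independently (log2 with a
pseudo-count, then quantile normalization across conditions, then
probe-to-gene averaging where applicable) and combined into a single
positive expression score per (gene, condition): the mean of the
normalized values over the datasets reporting that pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import InteractionRecord
from .networks import GlobalInteractionNetwork

__all__ = [
    "merge_interaction_datasets",
    "log2_transform",
    "quantile_normalize",
    "average_duplicate_probes",
    "build_expression_table",
    "ExpressionTable",
]

log = logging.getLogger(__name__)

#: weight an unweighted dataset contributes to the edge-weight average
UNWEIGHTED_REPORT_WEIGHT = 1.0


def merge_interaction_datasets(
    datasets: Mapping[str, Sequence[InteractionRecord]],
) -> GlobalInteractionNetwork:
    """Union the edges of named interaction datasets.

    Self-loops are dropped.  A dataset reporting the same unordered pair
    several times counts once (its weights for that pair are averaged
    first).
    """
    if not datasets:
        raise ValueError("at least one interaction dataset is required")
    names = tuple(datasets)
    n = len(names)
    graph = nx.Graph()
    # per edge: dataset -> list of reported weights (None = unweighted report)
    reports: dict[tuple[str, str], dict[str, list[float | None]]] = {}
    for name, records in datasets.items():
        for rec in records:
            if rec.gene_a == rec.gene_b:
                continue
            key = tuple(sorted((rec.gene_a, rec.gene_b)))
            reports.setdefault(key, {}).setdefault(name, []).append(rec.weight)
    for (a, b), per_dataset_raw in reports.items():
        per_dataset: dict[str, float | None] = {}
        for name, weights in per_dataset_raw.items():
            numeric = [w for w in weights if w is not None]
            per_dataset[name] = sum(numeric) / len(numeric) if numeric else None
        contributions = [
            UNWEIGHTED_REPORT_WEIGHT if w is None else w
            for w in per_dataset.values()
        ]
        graph.add_edge(
            a, b,
            per_dataset=per_dataset,
            avg_weight=sum(contributions) / len(contributions),
            coverage=len(per_dataset) / n,
        )
    return GlobalInteractionNetwork(graph=graph, dataset_names=names)


def log2_transform(matrix: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Replace every cell v by log2(v + offset); ``offset`` defaults to a
    pseudo-count of 1 so zero counts map to zero."""
    if (matrix.values < 0).any():
        raise ValueError("expression values must be non-negative")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if offset == 0 and (matrix.values == 0).any():
        raise ValueError("offset 0 with zero cells would produce -inf")
    return pd.DataFrame(
        np.log2(matrix.values + offset), index=matrix.index, columns=matrix.columns
    )


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across condition columns (Bolstad).

    After normalization every column holds the same multiset of values:
    the per-rank means of the sorted columns.  Ties within a column get
    the mean of the rank means they span, so the procedure is exact for
    tied data and idempotent.  A single-column matrix is returned
    unchanged with a warning.
    """
    if matrix.isna().values.any():
        raise ValueError("quantile normalization requires a complete matrix")
    if matrix.shape[1] < 2:
        log.warning("quantile normalization of a single column is the identity")
        return matrix.copy()
    values = matrix.values.astype(float)
    n_rows, n_cols = values.shape
    rank_means = np.sort(values, axis=0).mean(axis=1)
    normalized = np.empty_like(values)
    for j in range(n_cols):
        order = np.argsort(values[:, j], kind="mergesort")
        sorted_vals = values[order, j]
        i = 0
        while i < n_rows:
            k = i
            while k + 1 < n_rows and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            # a tie spanning ranks i..k receives the mean of those rank means
            normalized[order[i : k + 1], j] = rank_means[i : k + 1].mean()
            i = k + 1
    return pd.DataFrame(normalized, index=matrix.index, columns=matrix.columns)


def average_duplicate_probes(
    matrix: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse probe rows to gene rows by per-condition arithmetic mean.

    Probes absent from the mapping are dropped.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    mapped = matrix.loc[[p for p in matrix.index if p in probe_to_gene]]
    if mapped.empty:
        raise ValueError("no probe maps to a gene")
    genes = [str(probe_to_gene[p]).strip().upper() for p in mapped.index]
    out = mapped.groupby(genes, sort=False).mean()
    out.index.name = matrix.index.name
    return out


class ExpressionTable:
    """Per-(gene, condition) expression scores across datasets.

    Stores one normalized genes x conditions matrix per dataset (missing
    pairs are NaN).  The *score* of a pair is the mean over the datasets
    reporting it; a pair reported nowhere has no score.
    """

    def __init__(self, datasets: Mapping[str, pd.DataFrame]):
        if not datasets:
            raise ValueError("at least one expression dataset is required")
        self._datasets = {name: frame.astype(float) for name, frame in datasets.items()}

    @property
    def dataset_names(self) -> tuple[str, ...]:
        return tuple(self._datasets)

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for frame in self._datasets.values():
            for c in frame.columns:
                if c not in seen:
                    seen.append(c)
        return tuple(seen)

    def per_dataset_values(self, gene: str, condition: str) -> dict[str, float]:
        values: dict[str, float] = {}
        for name, frame in self._datasets.items():
            if gene in frame.index and condition in frame.columns:
                v = frame.at[gene, condition]
                if pd.notna(v):
                    values[name] = float(v)
        return values

    def score(self, gene: str, condition: str) -> float:
        values = self.per_dataset_values(gene, condition)
        if not values:
            raise KeyError(f"({gene}, {condition}) is not reported by any dataset")
        return float(np.mean(list(values.values())))

    def scores_for(self, condition: str) -> dict[str, float]:
        """All genes with a score in ``condition`` -> score."""
        frames = [
            frame[condition]
            for frame in self._datasets.values()
            if condition in frame.columns
        ]
        if not frames:
            return {}
        stacked = pd.concat(frames, axis=1)
        means = stacked.mean(axis=1, skipna=True)
        return {gene: float(v) for gene, v in means.items() if pd.notna(v)}

    def restrict(self, subset: Sequence[str]) -> "ExpressionTable":
        """Recompute scores over a subset of datasets only."""
        if not subset:
            raise ValueError("dataset subset must be non-empty")
        unknown = set(subset) - set(self._datasets)
        if unknown:
            raise KeyError(f"unknown expression dataset(s): {sorted(unknown)}")
        return ExpressionTable({name: self._datasets[name] for name in subset})


def build_expression_table(
    datasets: Mapping[str, pd.DataFrame],
) -> ExpressionTable:
    """Wrap named, already-normalized expression matrices as a score table."""
    return ExpressionTable(datasets)
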