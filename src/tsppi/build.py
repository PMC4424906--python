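"""Construct tissue/tumor-specific PPI networks from the global network
and the expression table.

A TS-PPI network for condition c is the subgraph of the global
gene-interaction network induced by the genes expressed in c, optionally
restricted by a gene list, an expression-score threshold, an interaction
weight threshold, a dataset-coverage threshold, and subsets of the
expression and interaction datasets.  All threshold comparisons are
inclusive (>=).  Expressed genes left without any surviving interaction
are excluded: the network is interaction-centric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .integrate import ExpressionTable
from .networks import GlobalInteractionNetwork, TSPPINetwork

__all__ = ["BuildFilter", "build_tsppi", "restrict_to_datasets"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BuildFilter:
    """Search filters for TS-PPI construction.

    ``conditions`` must be all tissues or all tumors; the package cannot
    infer the kind from a bare name, so the exclusion is enforced only
    when ``condition_kind`` metadata is supplied.
    """

    conditions: tuple[str, ...]
    gene_list: frozenset[str] | None = None
    expression_datasets: tuple[str, ...] | None = None
    interaction_datasets: tuple[str, ...] | None = None
    min_expression: float | None = None
    min_edge_weight: float | None = None
    min_coverage: float | None = None
    condition_kind: Mapping[str, str] | None = None

    def __post_init__(self):
        if not self.conditions:
            raise ValueError("at least one condition is required")
        if self.min_edge_weight is not None and not 0.0 <= self.min_edge_weight <= 1.0:
            raise ValueError("min_edge_weight must lie in [0, 1]")
        if self.min_coverage is not None and not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage must lie in [0, 1]")
        if self.condition_kind is not None:
            kinds = {self.condition_kind.get(c) for c in self.conditions}
            if len(kinds) > 1:
                raise ValueError(
                    "tissues and tumors are mutually exclusive in one build"
                )


def restrict_to_datasets(
    expr: ExpressionTable, subset: Sequence[str]
) -> ExpressionTable:
    """Expression scores recomputed over a subset of datasets only."""
    return expr.restrict(subset)


def build_tsppi(
    global_net: GlobalInteractionNetwork,
    expr: ExpressionTable,
    filt: BuildFilter,
) -> dict[str, TSPPINetwork]:
    """One TS-PPI network per requested condition.

    Node set: genes with an expression score in the condition (over the
    selected expression datasets), meeting ``min_expression`` and
    ``gene_list`` when set.  Edge set: global edges with both endpoints
    in the node set, meeting the weight/coverage thresholds and reported
    by at least one selected interaction dataset.  An empty result is a
    warning, not an error.
    """
    if filt.expression_datasets is not None:
        expr = expr.restrict(filt.expression_datasets)
    if filt.interaction_datasets is not None:
        unknown = set(filt.interaction_datasets) - set(global_net.dataset_names)
        if unknown:
            raise KeyError(f"unknown interaction dataset(s): {sorted(unknown)}")
    known_conditions = set(expr.conditions)
    networks: dict[str, TSPPINetwork] = {}
    for condition in filt.conditions:
        if condition not in known_conditions:
            raise KeyError(f"unknown condition {condition!r}")
        scores = expr.scores_for(condition)
        nodes = {
            gene: score
            for gene, score in scores.items()
            if (filt.gene_list is None or gene in filt.gene_list)
            and (filt.min_expression is None or score >= filt.min_expression)
        }
        graph = nx.Graph()
        for a, b, data in global_net.graph.edges(data=True):
            if a not in nodes or b not in nodes:
                continue
            if filt.min_edge_weight is not None and data["avg_weight"] < filt.min_edge_weight:
                continue
            if filt.min_coverage is not None and data["coverage"] < filt.min_coverage:
                continue
            if filt.interaction_datasets is not None and not (
                set(data["per_dataset"]) & set(filt.interaction_datasets)
            ):
                continue
            graph.add_edge(a, b, weight=data["avg_weight"],
                           coverage=data["coverage"], label=condition)
        for node in graph.nodes:
            graph.nodes[node]["weight"] = nodes[node]
        if graph.number_of_nodes() == 0:
            log.warning("TS-PPI network for %r is empty under the given filters",
                        condition)
        networks[condition] = TSPPINetwork(
            name=condition, conditions=(condition,), graph=graph
        )
    return networks
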