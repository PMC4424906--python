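"""Shared graph containers.

Two kinds of graphs flow through the package:

* the *global gene-interaction network*, the union of all interactions
  reported by at least one integrated dataset, with per-edge average
  weight and dataset coverage, and
* *tissue/tumor-specific PPI networks* (TS-PPI), node-weighted subgraphs
  in which both endpoints of every edge are expressed in the selected
  condition(s).

Both wrap a :class:`networkx.Graph`; attribute conventions are documented
on each class and enforced by ``validate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = ["GlobalInteractionNetwork", "TSPPINetwork"]


@dataclass
class GlobalInteractionNetwork:
    """Union of interaction datasets over gene symbols.

    Edge attributes:

    ``per_dataset``
        mapping dataset name -> weight in [0, 1], or ``None`` when the
        reporting dataset is unweighted.
    ``avg_weight``
        mean weight over reporting datasets; an unweighted report counts
        as 1.0 (a "certain" interaction).
    ``coverage``
        fraction of integrated datasets reporting the edge, in (0, 1].
    """

    graph: nx.Graph
    dataset_names: tuple[str, ...]

    @property
    def n_datasets(self) -> int:
        return len(self.dataset_names)

    def validate(self) -> None:
        n = self.n_datasets
        if n == 0:
            raise ValueError("global network must integrate at least one dataset")
        for a, b, data in self.graph.edges(data=True):
            if a == b:
                raise ValueError(f"self-loop on {a}")
            reporting = data["per_dataset"]
            if not reporting:
                raise ValueError(f"edge {a}-{b} reported by no dataset")
            if not set(reporting) <= set(self.dataset_names):
                raise ValueError(f"edge {a}-{b} names unknown datasets")
            cov = len(reporting) / n
            if abs(cov - data["coverage"]) > 1e-12:
                raise ValueError(f"edge {a}-{b}: inconsistent coverage")
            if not 0.0 < data["avg_weight"] <= 1.0:
                raise ValueError(f"edge {a}-{b}: avg_weight outside (0, 1]")


@dataclass
class TSPPINetwork:
    """Node-weighted, edge-weighted simple graph for one tissue/tumor selection.

    Node attribute ``weight`` holds the gene's (positive) expression score
    in the network's condition(s); edge attributes ``weight`` (interaction
    confidence in [0, 1]) and ``label`` (tissue string) mirror the
    tab-separated network file format.
    """

    name: str
    conditions: tuple[str, ...]
    graph: nx.Graph = field(default_factory=nx.Graph)

    def node_weight(self, node: str) -> float:
        return self.graph.nodes[node]["weight"]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        """Check the TS-PPI defining invariants (simple graph, positive
        node weights, every edge endpoint expressed)."""
        for node, data in self.graph.nodes(data=True):
            w = data.get("weight")
            if w is None or not w > 0:
                raise ValueError(f"node {node} lacks a positive expression score")
        for a, b, data in self.graph.edges(data=True):
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if not 0.0 <= data.get("weight", 0.0) <= 1.0:
                raise ValueError(f"edge {a}-{b}: weight outside [0, 1]")
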