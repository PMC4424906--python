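"""Homology schemes: which nodes of different networks may be aligned.

The default scheme is label identity — two nodes are homologs when they
carry the same gene symbol, with score 1.0.  Alternatively a score table
loaded from a homology file assigns positive scores to explicit node
pairs across networks.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from typing import Iterable

__all__ = ["HomologyScheme", "LabelIdentity", "HomologyTable"]

NodeRef = tuple[str, str]  # (node label, network name)


class HomologyScheme(ABC):
    @abstractmethod
    def score(self, node_a: str, net_a: str, node_b: str, net_b: str) -> float:
        """Homology score for a cross-network node pair; 0.0 = not homologous."""

    def homologous(self, node_a: str, net_a: str, node_b: str, net_b: str) -> bool:
        return self.score(node_a, net_a, node_b, net_b) > 0.0

    @abstractmethod
    def partners(self, node: str, net: str, other_net: str,
                 candidates: Iterable[str]) -> list[str]:
        """Nodes of ``other_net`` (drawn from ``candidates``) homologous to
        ``node`` of ``net``."""


class LabelIdentity(HomologyScheme):
    """Same gene symbol on different networks => homologs, score 1.0."""

    def score(self, node_a: str, net_a: str, node_b: str, net_b: str) -> float:
        return 1.0 if node_a == node_b else 0.0

    def partners(self, node, net, other_net, candidates):
        return [node] if node in set(candidates) else []


class HomologyTable(HomologyScheme):
    """Symmetric score map built from a homology file."""

    def __init__(self, scores: dict[tuple[NodeRef, NodeRef], float]):
        self._scores: dict[tuple[NodeRef, NodeRef], float] = {}
        self._partners: dict[tuple[NodeRef, str], set[str]] = {}
        for (ref_a, ref_b), s in scores.items():
            self.add(ref_a, ref_b, s)

    def add(self, ref_a: NodeRef, ref_b: NodeRef, score: float) -> None:
        if not score > 0:
            raise ValueError("homology scores must be positive")
        if ref_a[1] == ref_b[1]:
            raise ValueError("homology pairs must span two different networks")
        self._scores[(ref_a, ref_b)] = score
        self._scores[(ref_b, ref_a)] = score
        self._partners.setdefault((ref_a, ref_b[1]), set()).add(ref_b[0])
        self._partners.setdefault((ref_b, ref_a[1]), set()).add(ref_a[0])

    def __len__(self) -> int:
        return len(self._scores) // 2

    def score(self, node_a, net_a, node_b, net_b):
        return self._scores.get(((node_a, net_a), (node_b, net_b)), 0.0)

    def partners(self, node, net, other_net, candidates):
        known = self._partners.get(((node, net), other_net), set())
        return sorted(known & set(candidates))
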