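"""Stochastic multiple differential local alignment of TS-PPI networks.

Given N node-weighted TS-PPI networks, the algorithm extracts sets of
conserved connected subnetworks (one per network) whose aligned genes
maximize cross-network expression divergence.  Divergence of a pair of
genes is the absolute log2 ratio of their expression scores (*LogFold*);
a column of aligned genes G = {G_1, ..., G_N} is scored by *MaxLogFold*,
the maximum LogFold over all pairs in the column.

The search is a seed-and-extend scheme driven by Gibbs sampling:

* *bootstrap* — sample an initial column among candidate nodes having
  homologs in every network and degree >= sigma, proportionally to a
  node-similarity score combining expression divergence, homology and
  topology;
* *iterative phase* — ``refine_iterations`` rounds of extension followed
  by one removal.  Extension repeatedly samples a new column adjacent to
  the aligned subgraphs and accepts it as long as the alignment's
  average MaxLogFold stays at or above ``max_logfold_threshold``;
  removal deletes the column with minimal MaxLogFold (skipping columns
  whose removal would disconnect a subnetwork);
* *post-processing* — alignments below the minimum size are discarded,
  the rest are ranked by the Index of Structural Conservation (ISC, the
  fraction of aligned node-pair interactions conserved in *all*
  networks), and highly overlapping alignments are pruned greedily.

The number of Gibbs iterations without change after which a chain is
considered converged is k = max k' : ((N-1)/N)^k' > alpha — the longest
run for which the probability that some network was never re-sampled
still exceeds alpha.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np

from .homology import HomologyScheme, HomologyTable, LabelIdentity
from .networks import TSPPINetwork

__all__ = [
    "AlignmentParameters",
    "AlignmentColumn",
    "Alignment",
    "log_fold",
    "max_log_fold",
    "gibbs_iteration_budget",
    "node_similarity",
    "bootstrap_seed",
    "extend",
    "remove_worst",
    "isc",
    "prune_overlaps",
    "rank_alignments",
    "align",
]

#: expression values at or below this are clamped before taking ratios,
#: so near-zero scores cannot produce infinite folds
EXPRESSION_CLAMP = 1e-6


@dataclass(frozen=True)
class AlignmentParameters:
    """Tunable parameters of the differential aligner.

    ``sigma`` (minimum seed-candidate degree), ``alpha`` (Gibbs
    convergence probability threshold), ``overlap_threshold``,
    ``refine_iterations``, ``min_alignment_size`` and
    ``max_logfold_threshold`` follow the tool's documented defaults.
    ``attempts`` (independent seeded runs), ``epsilon`` (similarity guard
    so equal-expression columns stay sampleable) and
    ``max_gibbs_iterations`` (hard cap on a chain that never satisfies
    the convergence rule) are additions of this package.
    """

    sigma: int = 1
    alpha: float = 0.05
    overlap_threshold: float = 0.5
    refine_iterations: int = 10
    min_alignment_size: int = 3
    max_logfold_threshold: float = 0.6
    attempts: int = 50
    seed: int = 0
    epsilon: float = 0.01
    max_gibbs_iterations: int | None = None  # default: 50 * k

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if not 0.0 <= self.overlap_threshold <= 1.0:
            raise ValueError("overlap_threshold must lie in [0, 1]")
        if self.refine_iterations < 1 or self.min_alignment_size < 1 or self.attempts < 1:
            raise ValueError("refine_iterations, min_alignment_size and attempts "
                             "must be positive")
        if self.max_logfold_threshold < 0:
            raise ValueError("max_logfold_threshold must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class AlignmentColumn:
    """One aligned gene per network, with the column's MaxLogFold."""

    members: tuple[str, ...]
    max_logfold: float


class Alignment:
    """An ordered set of aligned columns over a fixed family of networks."""

    def __init__(self, networks: Sequence[TSPPINetwork],
                 columns: Sequence[AlignmentColumn] = ()):
        self.networks: tuple[TSPPINetwork, ...] = tuple(networks)
        self.columns: list[AlignmentColumn] = list(columns)
        self.isc: float = 0.0

    @property
    def network_names(self) -> tuple[str, ...]:
        return tuple(net.name for net in self.networks)

    @property
    def size(self) -> int:
        return len(self.columns)

    @property
    def avg_max_logfold(self) -> float:
        if not self.columns:
            return 0.0
        return sum(col.max_logfold for col in self.columns) / len(self.columns)

    def members_of(self, i: int) -> list[str]:
        """Aligned nodes of the i-th network, in column order."""
        return [col.members[i] for col in self.columns]

    @property
    def subgraphs(self) -> dict[str, nx.Graph]:
        """Per-network induced subgraphs (copies, keyed by network name)."""
        return {
            net.name: net.graph.subgraph(self.members_of(i)).copy()
            for i, net in enumerate(self.networks)
        }

    def sort_key(self) -> tuple:
        return tuple(sorted(col.members for col in self.columns))

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Alignment(size={self.size}, avg_max_logfold="
                f"{self.avg_max_logfold:.3f}, isc={self.isc:.3f})")


# ---------------------------------------------------------------------------
# scoring primitives


def log_fold(expr_a: float, expr_b: float,
             epsilon: float = EXPRESSION_CLAMP) -> float:
    """Absolute log2 expression ratio of two genes.

    Symmetric in its arguments and zero iff they are equal; values at or
    below ``epsilon`` are clamped to ``epsilon`` first.
    """
    if math.isnan(expr_a) or math.isnan(expr_b):
        raise ValueError("expression values must not be NaN")
    a = max(float(expr_a), epsilon)
    b = max(float(expr_b), epsilon)
    hi, lo = (a, b) if a >= b else (b, a)
    return math.log2(hi / lo)


def max_log_fold(column_weights: Sequence[float]) -> float:
    """Maximum LogFold over all pairs of a column: log_fold(max, min)."""
    if len(column_weights) < 2:
        raise ValueError("MaxLogFold needs at least two expression values")
    return log_fold(max(column_weights), min(column_weights))


def gibbs_iteration_budget(n_networks: int, alpha: float) -> int:
    """Largest k' with ((N-1)/N)^k' > alpha (strict).

    ((N-1)/N)^k' is the probability that a given network's member was
    never re-drawn in k' consecutive single-site iterations; sampling
    stops once the state is unchanged for k consecutive iterations.
    """
    if n_networks < 2:
        raise ValueError("at least two networks are required")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    ratio = (n_networks - 1) / n_networks
    k = 0
    p = ratio
    while p > alpha:
        k += 1
        p *= ratio
    return k


def _column_weights(members: Sequence[str],
                    networks: Sequence[TSPPINetwork]) -> list[float]:
    return [net.node_weight(m) for net, m in zip(networks, members)]


def _homology_score(members: Sequence[str], names: Sequence[str],
                    homology: HomologyScheme) -> float:
    """Mean pairwise homology score; 0.0 if any pair is non-homologous."""
    total, pairs = 0.0, 0
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            s = homology.score(members[i], names[i], members[j], names[j])
            if s <= 0.0:
                return 0.0
            total += s
            pairs += 1
    return total / pairs


def _topology_score(members: Sequence[str],
                    networks: Sequence[TSPPINetwork],
                    alignment: Alignment | None) -> float:
    """1 + number of aligned columns connected to ``members`` by an edge
    conserved in every network."""
    score = 1.0
    if alignment is None:
        return score
    for col in alignment.columns:
        if all(net.graph.has_edge(m, c)
               for net, m, c in zip(networks, members, col.members)):
            score += 1.0
    return score


def node_similarity(candidate: Sequence[str] | AlignmentColumn,
                    homology: HomologyScheme,
                    networks: Sequence[TSPPINetwork],
                    current_alignment: Alignment | None = None,
                    epsilon: float = 0.01) -> float:
    """Sampling weight of a candidate column:
    (epsilon + MaxLogFold) * homology score * topology score.

    Strictly positive for homologous columns, so every candidate keeps a
    nonzero selection probability even with identical expression values.
    """
    members = candidate.members if isinstance(candidate, AlignmentColumn) else tuple(candidate)
    names = [net.name for net in networks]
    hom = _homology_score(members, names, homology)
    if hom <= 0.0:
        raise ValueError(f"column {members} is not mutually homologous")
    mlf = max_log_fold(_column_weights(members, networks))
    topo = _topology_score(members, networks, current_alignment)
    return (epsilon + mlf) * hom * topo


# ---------------------------------------------------------------------------
# candidate-column enumeration and Gibbs sampling


def _enumerate_columns(eligible: Sequence[Sequence[str]],
                       names: Sequence[str],
                       homology: HomologyScheme) -> list[tuple[str, ...]]:
    """All columns (one member per network, pairwise homologous) over the
    given per-network eligible node sets, in deterministic order."""
    if isinstance(homology, LabelIdentity):
        common = set(eligible[0])
        for nodes in eligible[1:]:
            common &= set(nodes)
        return [(label,) * len(eligible) for label in sorted(common)]
    columns: list[tuple[str, ...]] = []

    def grow(partial: tuple[str, ...]) -> None:
        i = len(partial)
        if i == len(eligible):
            columns.append(partial)
            return
        for node in sorted(eligible[i]):
            if all(homology.homologous(prev, names[j], node, names[i])
                   for j, prev in enumerate(partial)):
                grow(partial + (node,))

    grow(())
    return columns


def _sample(cumulative: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.searchsorted(cumulative, rng.random() * cumulative[-1],
                               side="right"))


def _gibbs_select(columns: list[tuple[str, ...]],
                  weights: np.ndarray,
                  homology: HomologyScheme,
                  k: int,
                  cap: int,
                  rng: np.random.Generator) -> tuple[str, ...]:
    """Run a Gibbs chain over candidate columns and return its final state.

    One iteration re-samples the member of one randomly chosen network
    proportionally to the similarity of the resulting column.  Under
    label identity a member replacement re-snaps the whole column to the
    new label, so the move set is the full candidate list; under a
    homology table only columns differing at the chosen position are
    reachable.  The chain stops when unchanged for ``k`` consecutive
    iterations, or after ``cap`` iterations.
    """
    n_networks = len(columns[0])
    if len(columns) == 1:
        return columns[0]
    label_scheme = isinstance(homology, LabelIdentity)
    if label_scheme:
        full_cumulative = np.cumsum(weights)
        groups = None
    else:
        groups = [defaultdict(list) for _ in range(n_networks)]
        for idx, col in enumerate(columns):
            for i in range(n_networks):
                groups[i][col[:i] + col[i + 1:]].append(idx)
    state = int(rng.integers(len(columns)))
    unchanged = 0
    for _ in range(cap):
        i = int(rng.integers(n_networks))
        if label_scheme:
            new = _sample(full_cumulative, rng)
        else:
            key = columns[state][:i] + columns[state][i + 1:]
            pool = groups[i][key]
            if len(pool) == 1:
                new = state
            else:
                new = pool[_sample(np.cumsum(weights[pool]), rng)]
        unchanged = unchanged + 1 if new == state else 0
        state = new
        if unchanged >= k:
            break
    return columns[state]


def _similarity_vector(columns: list[tuple[str, ...]],
                       networks: Sequence[TSPPINetwork],
                       homology: HomologyScheme,
                       alignment: Alignment | None,
                       epsilon: float,
                       mlf_cache: dict | None = None) -> np.ndarray:
    """Vectorized ``node_similarity`` over pre-validated candidate columns.

    Topology is counted by intersecting, across networks, the sets of
    aligned-column indices adjacent to the candidate's member — identical
    to the reference formula but avoiding the per-pair edge scan.
    """
    names = [net.name for net in networks]
    label_scheme = isinstance(homology, LabelIdentity)
    if alignment is not None and alignment.columns:
        aligned_index: list[dict[str, int]] | None = [
            {col.members[i]: j for j, col in enumerate(alignment.columns)}
            for i in range(len(networks))
        ]
    else:
        aligned_index = None
    out = np.empty(len(columns), dtype=float)
    for idx, members in enumerate(columns):
        if mlf_cache is not None and members in mlf_cache:
            mlf = mlf_cache[members]
        else:
            mlf = max_log_fold(_column_weights(members, networks))
            if mlf_cache is not None:
                mlf_cache[members] = mlf
        hom = 1.0 if label_scheme else _homology_score(members, names, homology)
        topo = 1.0
        if aligned_index is not None:
            common: set[int] | None = None
            for i, net in enumerate(networks):
                index = aligned_index[i]
                hits = {index[v] for v in net.graph.adj[members[i]] if v in index}
                common = hits if common is None else common & hits
                if not common:
                    break
            topo += len(common) if common else 0
        out[idx] = (epsilon + mlf) * hom * topo
    return out


class _NoSeedCandidates(ValueError):
    pass


def _seed_pool(networks: Sequence[TSPPINetwork],
               homology: HomologyScheme,
               params: AlignmentParameters) -> list[tuple[str, ...]]:
    eligible = []
    for net in networks:
        nodes = [n for n in net.graph.nodes if net.graph.degree(n) >= params.sigma]
        if not nodes:
            raise _NoSeedCandidates(
                f"no seed candidates in network {net.name!r} with degree >= {params.sigma}"
            )
        eligible.append(nodes)
    columns = _enumerate_columns(eligible, [n.name for n in networks], homology)
    if not columns:
        raise _NoSeedCandidates("no mutually homologous seed column exists")
    return columns


def bootstrap_seed(networks: Sequence[TSPPINetwork],
                   homology: HomologyScheme,
                   params: AlignmentParameters,
                   rng: np.random.Generator,
                   _pool: list[tuple[str, ...]] | None = None,
                   _weights: np.ndarray | None = None) -> AlignmentColumn:
    """Sample an initial alignment column by Gibbs sampling over the
    mutually homologous columns of sufficiently connected nodes."""
    columns = _pool if _pool is not None else _seed_pool(networks, homology, params)
    weights = (_weights if _weights is not None else
               _similarity_vector(columns, networks, homology, None, params.epsilon))
    k = gibbs_iteration_budget(len(networks), params.alpha)
    cap = params.max_gibbs_iterations or 50 * k
    members = _gibbs_select(columns, weights, homology, k, cap, rng)
    return AlignmentColumn(members, max_log_fold(_column_weights(members, networks)))


def _extension_columns(alignment: Alignment,
                       homology: HomologyScheme) -> list[tuple[str, ...]]:
    """Candidate columns whose member in each network is an unused
    neighbor of that network's aligned subgraph."""
    eligible = []
    for i, net in enumerate(alignment.networks):
        used = set(alignment.members_of(i))
        frontier: set[str] = set()
        for node in used:
            frontier.update(net.graph.neighbors(node))
        frontier -= used
        if not frontier:
            return []
        eligible.append(sorted(frontier))
    return _enumerate_columns(eligible, alignment.network_names, homology)


def extend(alignment: Alignment,
           networks: Sequence[TSPPINetwork],
           homology: HomologyScheme,
           params: AlignmentParameters,
           rng: np.random.Generator,
           _mlf_cache: dict | None = None) -> Alignment:
    """Grow the alignment while its average MaxLogFold stays at or above
    the threshold.

    Each step Gibbs-samples one adjacent unused column proportionally to
    node similarity and accepts it only if the resulting average
    MaxLogFold >= ``max_logfold_threshold``; the first rejection (or an
    empty candidate set in some network) ends the extension.  Per-network
    connectivity is preserved by construction.
    """
    if not alignment.columns:
        raise ValueError("cannot extend an empty alignment")
    k = gibbs_iteration_budget(len(networks), params.alpha)
    cap = params.max_gibbs_iterations or 50 * k
    total = alignment.avg_max_logfold * alignment.size
    while True:
        candidates = _extension_columns(alignment, homology)
        if not candidates:
            break
        weights = _similarity_vector(candidates, networks, homology,
                                     alignment, params.epsilon, _mlf_cache)
        members = _gibbs_select(candidates, weights, homology, k, cap, rng)
        mlf = max_log_fold(_column_weights(members, networks))
        if (total + mlf) / (alignment.size + 1) < params.max_logfold_threshold:
            break
        alignment.columns.append(AlignmentColumn(members, mlf))
        total += mlf
    return alignment


def remove_worst(alignment: Alignment) -> Alignment:
    """Delete the column with minimal MaxLogFold.

    A column whose removal would disconnect any per-network subnetwork is
    skipped and the smallest *removable* column is deleted instead; ties
    break lexicographically on member labels.  Alignments of size < 2 are
    returned unchanged.
    """
    if alignment.size < 2:
        return alignment
    order = sorted(range(alignment.size),
                   key=lambda idx: (alignment.columns[idx].max_logfold,
                                    alignment.columns[idx].members))
    for idx in order:
        if _removal_keeps_connected(alignment, idx):
            del alignment.columns[idx]
            return alignment
    return alignment


def _removal_keeps_connected(alignment: Alignment, idx: int) -> bool:
    for i, net in enumerate(alignment.networks):
        remaining = [col.members[i]
                     for j, col in enumerate(alignment.columns) if j != idx]
        sub = net.graph.subgraph(remaining)
        if sub.number_of_nodes() > 0 and not nx.is_connected(sub):
            return False
    return True


def isc(alignment: Alignment,
        networks: Sequence[TSPPINetwork] | None = None) -> float:
    """Index of Structural Conservation: the fraction of aligned column
    pairs whose interaction, present in at least one network, is present
    in *all* networks.  An alignment without any present pair scores 0."""
    nets = tuple(networks) if networks is not None else alignment.networks
    conserved = present = 0
    cols = alignment.columns
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            hits = sum(
                1 for net, a, b in zip(nets, cols[i].members, cols[j].members)
                if net.graph.has_edge(a, b)
            )
            if hits > 0:
                present += 1
                if hits == len(nets):
                    conserved += 1
    return conserved / present if present else 0.0


# ---------------------------------------------------------------------------
# post-processing


def _overlap(a: Alignment, b: Alignment) -> float:
    values = []
    for i in range(len(a.networks)):
        nodes_a, nodes_b = set(a.members_of(i)), set(b.members_of(i))
        denom = min(len(nodes_a), len(nodes_b))
        values.append(len(nodes_a & nodes_b) / denom if denom else 0.0)
    return sum(values) / len(values)


def prune_overlaps(alignments: Sequence[Alignment],
                   overlap_threshold: float) -> list[Alignment]:
    """Greedy sweep in rank order: keep an alignment iff its average
    per-network overlap with every kept alignment is <= the threshold."""
    kept: list[Alignment] = []
    for alignment in alignments:
        if all(_overlap(alignment, other) <= overlap_threshold for other in kept):
            kept.append(alignment)
    return kept


def rank_alignments(alignments: Sequence[Alignment]) -> list[Alignment]:
    """Descending ISC, ties by descending average MaxLogFold, then by
    descending size, then lexicographically on member labels."""
    return sorted(
        alignments,
        key=lambda a: (-a.isc, -a.avg_max_logfold, -a.size, a.sort_key()),
    )


def align(networks: Sequence[TSPPINetwork],
          homology: HomologyScheme | None = None,
          params: AlignmentParameters | None = None) -> list[Alignment]:
    """Full differential local alignment of two or more TS-PPI networks.

    Runs ``params.attempts`` independent seeded alignments (bootstrap,
    then ``refine_iterations`` rounds of extend + remove, then a final
    extend), drops alignments below the minimum size, scores the rest
    (ISC, average MaxLogFold), ranks them and prunes overlaps.  The same
    parameters and seed always produce the same result.
    """
    networks = tuple(networks)
    if len(networks) < 2:
        raise ValueError("at least two networks are required")
    for net in networks:
        if net.graph.number_of_nodes() == 0:
            raise ValueError(f"network {net.name!r} is empty")
    if len(set(net.name for net in networks)) != len(networks):
        raise ValueError("network names must be unique")
    homology = homology if homology is not None else LabelIdentity()
    if isinstance(homology, HomologyTable) and len(homology) == 0:
        raise ValueError("homology table is empty")
    params = params if params is not None else AlignmentParameters()
    rng = np.random.default_rng(params.seed)

    mlf_cache: dict = {}
    pool = _seed_pool(networks, homology, params)
    pool_weights = _similarity_vector(pool, networks, homology, None,
                                      params.epsilon, mlf_cache)

    results: list[Alignment] = []
    for _ in range(params.attempts):
        seed_col = bootstrap_seed(networks, homology, params, rng,
                                  _pool=pool, _weights=pool_weights)
        alignment = Alignment(networks, [seed_col])
        for _ in range(params.refine_iterations):
            extend(alignment, networks, homology, params, rng, mlf_cache)
            remove_worst(alignment)
        extend(alignment, networks, homology, params, rng, mlf_cache)
        if alignment.size >= params.min_alignment_size:
            alignment.isc = isc(alignment)
            results.append(alignment)
    ranked = rank_alignments(results)
    return prune_overlaps(ranked, params.overlap_threshold)
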