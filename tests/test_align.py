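import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tsppi
from tsppi import AlignmentParameters, HomologyTable, LabelIdentity
from tsppi.align import Alignment, AlignmentColumn

from conftest import make_network

positive = st.floats(min_value=1e-3, max_value=1e6,
                     allow_nan=False, allow_infinity=False)


class TestLogFold:
    @pytest.mark.parametrize("a, b, expected", [
        (8, 4, 1.0), (5, 5, 0.0), (2, 16, 3.0), (16, 2, 3.0),
    ])
    def test_examples(self, a, b, expected):
        assert tsppi.log_fold(a, b) == pytest.approx(expected)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            tsppi.log_fold(float("nan"), 1.0)

    def test_near_zero_values_are_clamped(self):
        assert math.isfinite(tsppi.log_fold(0.0, 5.0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(positive, positive)
    def test_symmetric_nonnegative_zero_iff_equal(self, a, b):
        fold = tsppi.log_fold(a, b)
        assert fold == tsppi.log_fold(b, a)
        assert fold >= 0.0
        assert (fold == 0.0) == (a == b)


class TestMaxLogFold:
    @pytest.mark.parametrize("values, expected", [
        ((8, 4, 2), 2.0), ((3, 3, 3), 0.0), ((8, 4), 1.0),
    ])
    def test_examples(self, values, expected):
        assert tsppi.max_log_fold(values) == pytest.approx(expected)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            tsppi.max_log_fold([5.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(positive, min_size=2, max_size=8))
    def test_equals_pairwise_enumeration(self, values):
        brute = max(tsppi.log_fold(a, b)
                    for a, b in itertools.combinations(values, 2))
        assert tsppi.max_log_fold(values) == pytest.approx(brute)


class TestGibbsIterationBudget:
    @pytest.mark.parametrize("n, alpha, expected", [(2, 0.05, 4), (4, 0.05, 10)])
    def test_anchor_values(self, n, alpha, expected):
        assert tsppi.gibbs_iteration_budget(n, alpha) == expected

    def test_matches_exhaustive_search(self):
        for n in range(2, 11):
            ratio = (n - 1) / n
            for alpha in (0.01, 0.05, 0.1, 0.2):
                expected = max(k for k in range(1, 10**4) if ratio**k > alpha)
                assert tsppi.gibbs_iteration_budget(n, alpha) == expected

    def test_smaller_alpha_never_decreases_k(self):
        for n in (2, 5, 9):
            budgets = [tsppi.gibbs_iteration_budget(n, a)
                       for a in (0.2, 0.1, 0.05, 0.01)]
            assert budgets == sorted(budgets)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            tsppi.gibbs_iteration_budget(3, alpha)


class TestNodeSimilarity:
    def nets(self, w1, w2):
        return (make_network("net1", {"A": w1, "B": 2.0}, [("A", "B", 0.5)]),
                make_network("net2", {"A": w2, "B": 2.0}, [("A", "B", 0.5)]))

    def test_equal_expression_column_keeps_positive_weight(self):
        nets = self.nets(5.0, 5.0)
        sim = tsppi.node_similarity(("A", "A"), LabelIdentity(), nets,
                                    epsilon=0.01)
        assert sim == pytest.approx(0.01)

    def test_similarity_linear_in_max_logfold(self):
        lo = tsppi.node_similarity(("A", "A"), LabelIdentity(),
                                   self.nets(4.0, 8.0), epsilon=1e-12)
        hi = tsppi.node_similarity(("A", "A"), LabelIdentity(),
                                   self.nets(4.0, 16.0), epsilon=1e-12)
        assert hi / lo == pytest.approx(2.0, rel=1e-6)

    def test_topology_base_value_without_aligned_neighbors(self):
        nets = self.nets(4.0, 8.0)
        unattached = Alignment(nets, [AlignmentColumn(("B", "B"), 0.0)])
        # B is adjacent to A in both networks -> one conserved attachment
        attached = tsppi.node_similarity(("A", "A"), LabelIdentity(), nets,
                                         current_alignment=unattached)
        alone = tsppi.node_similarity(("A", "A"), LabelIdentity(), nets)
        assert attached == pytest.approx(2 * alone)

    def test_non_homologous_column_rejected(self):
        nets = self.nets(4.0, 8.0)
        table = HomologyTable({(("B", "net1"), ("B", "net2")): 1.0})
        with pytest.raises(ValueError, match="homologous"):
            tsppi.node_similarity(("A", "A"), table, nets)


class TestBootstrapSeed:
    def test_unique_homologous_column_is_forced(self, rng):
        nets = (make_network("net1", {"A": 5, "B": 7}, [("A", "B", 0.5)]),
                make_network("net2", {"C": 5, "D": 7}, [("C", "D", 0.5)]))
        table = HomologyTable({(("A", "net1"), ("C", "net2")): 1.0})
        col = tsppi.bootstrap_seed(nets, table, AlignmentParameters(), rng)
        assert col.members == ("A", "C")

    def test_sigma_above_max_degree_is_an_error(self, rng, planted_pair):
        params = AlignmentParameters(sigma=10)
        with pytest.raises(ValueError, match="seed candidates"):
            tsppi.bootstrap_seed(planted_pair, LabelIdentity(), params, rng)

    def test_fixed_seed_reproducible(self, planted_pair):
        params = AlignmentParameters()
        cols = [
            tsppi.bootstrap_seed(planted_pair, LabelIdentity(), params,
                                 np.random.default_rng(99))
            for _ in range(2)
        ]
        assert cols[0] == cols[1]


class TestExtend:
    def test_grows_by_the_only_high_fold_column(self, planted_pair, rng):
        params = AlignmentParameters(max_logfold_threshold=1.9)
        alignment = Alignment(planted_pair, [AlignmentColumn(("A", "A"), 2.0)])
        tsppi.extend(alignment, planted_pair, LabelIdentity(), params, rng)
        assert sorted(col.members[0] for col in alignment.columns) == ["A", "B", "C"]

    def test_unreachable_threshold_leaves_alignment_unchanged(self, planted_pair, rng):
        params = AlignmentParameters(max_logfold_threshold=1e9)
        alignment = Alignment(planted_pair, [AlignmentColumn(("A", "A"), 2.0)])
        tsppi.extend(alignment, planted_pair, LabelIdentity(), params, rng)
        assert alignment.size == 1

    def test_subgraphs_stay_connected(self, planted_pair, rng):
        params = AlignmentParameters(max_logfold_threshold=0.1)
        alignment = Alignment(planted_pair, [AlignmentColumn(("A", "A"), 2.0)])
        tsppi.extend(alignment, planted_pair, LabelIdentity(), params, rng)
        assert alignment.size > 1
        for sub in alignment.subgraphs.values():
            assert nx.is_connected(sub)

    def test_empty_alignment_rejected(self, planted_pair, rng):
        with pytest.raises(ValueError):
            tsppi.extend(Alignment(planted_pair), planted_pair, LabelIdentity(),
                         AlignmentParameters(), rng)


def path_alignment(folds):
    """Alignment along a path A-B-C with prescribed per-column folds,
    realized through node weights on two path networks."""
    weights1 = {"A": 2 ** folds[0], "B": 2 ** folds[1], "C": 2 ** folds[2]}
    weights2 = {"A": 1.0, "B": 1.0, "C": 1.0}
    edges = [("A", "B", 0.5), ("B", "C", 0.5)]
    nets = (make_network("net1", weights1, edges),
            make_network("net2", weights2, edges))
    columns = [AlignmentColumn((n, n), folds[i])
               for i, n in enumerate(("A", "B", "C"))]
    return Alignment(nets, columns)


class TestRemoveWorst:
    def test_minimal_column_removed_when_removable(self):
        # triangle: every column is removable
        edges = [("A", "B", 1), ("B", "C", 1), ("A", "C", 1)]
        nets = (make_network("net1", {"A": 4, "B": 1.07, "C": 2.83}, edges),
                make_network("net2", {"A": 1, "B": 1, "C": 1}, edges))
        columns = [AlignmentColumn(("A", "A"), 2.0),
                   AlignmentColumn(("B", "B"), 0.1),
                   AlignmentColumn(("C", "C"), 1.5)]
        alignment = Alignment(nets, columns)
        tsppi.remove_worst(alignment)
        assert [c.members[0] for c in alignment.columns] == ["A", "C"]

    def test_cut_column_is_skipped(self):
        # on a path the minimal column B is the middle node; removing it
        # would disconnect A and C, so the smallest end column goes instead
        alignment = path_alignment([2.0, 0.1, 1.5])
        tsppi.remove_worst(alignment)
        assert sorted(c.members[0] for c in alignment.columns) == ["A", "B"]

    def test_single_column_unchanged(self, planted_pair):
        alignment = Alignment(planted_pair, [AlignmentColumn(("A", "A"), 2.0)])
        assert tsppi.remove_worst(alignment).size == 1


class TestISC:
    def test_triangle_to_triangle_fully_conserved(self):
        edges = [("A", "B", 1), ("B", "C", 1), ("A", "C", 1)]
        nets = (make_network("net1", {"A": 1, "B": 1, "C": 1}, edges),
                make_network("net2", {"A": 1, "B": 1, "C": 1}, edges))
        alignment = Alignment(nets, [AlignmentColumn((n, n), 0.0)
                                     for n in "ABC"])
        assert tsppi.isc(alignment) == 1.0

    def test_partially_conserved_pair(self):
        nets = (make_network("net1", {"A": 1, "B": 1, "C": 1},
                             [("A", "B", 1), ("B", "C", 1)]),
                make_network("net2", {"A": 1, "B": 1, "C": 1},
                             [("A", "B", 1)]))
        alignment = Alignment(nets, [AlignmentColumn((n, n), 0.0)
                                     for n in "ABC"])
        assert tsppi.isc(alignment) == pytest.approx(0.5)

    def test_no_present_pair_scores_zero(self):
        nets = (make_network("net1", {"A": 1, "B": 1}, []),
                make_network("net2", {"A": 1, "B": 1}, []))
        alignment = Alignment(nets, [AlignmentColumn((n, n), 0.0) for n in "AB"])
        assert tsppi.isc(alignment) == 0.0


class TestPostProcessing:
    def fake(self, members_by_net, isc_value, fold):
        nets = tuple(
            make_network(f"net{i + 1}", {m: 1.0 for m in members}, [])
            for i, members in enumerate(members_by_net)
        )
        columns = [AlignmentColumn(col, fold)
                   for col in zip(*members_by_net)]
        alignment = Alignment(nets, columns)
        alignment.isc = isc_value
        return alignment

    def test_disjoint_alignments_all_kept(self):
        a = self.fake([("A", "B"), ("A", "B")], 1.0, 1.0)
        b = self.fake([("X", "Y"), ("X", "Y")], 0.5, 1.0)
        assert tsppi.prune_overlaps([a, b], 0.0) == [a, b]

    def test_duplicates_removed_at_default_threshold(self):
        a = self.fake([("A", "B"), ("A", "B")], 1.0, 1.0)
        b = self.fake([("A", "B"), ("A", "B")], 0.9, 1.0)
        assert tsppi.prune_overlaps([a, b], 0.5) == [a]

    def test_threshold_one_keeps_everything(self):
        a = self.fake([("A", "B"), ("A", "B")], 1.0, 1.0)
        b = self.fake([("A", "B"), ("A", "B")], 0.9, 1.0)
        assert tsppi.prune_overlaps([a, b], 1.0) == [a, b]

    def test_ranking_by_isc_then_fold_then_size(self):
        high_isc = self.fake([("A", "B"), ("A", "B")], 0.9, 1.0)
        low_isc = self.fake([("C", "D"), ("C", "D")], 0.4, 9.0)
        high_fold = self.fake([("E", "F"), ("E", "F")], 0.9, 2.0)
        ranked = tsppi.rank_alignments([low_isc, high_isc, high_fold])
        assert ranked == [high_fold, high_isc, low_isc]


def assert_structurally_valid(alignment, params, n_networks):
    for i in range(n_networks):
        members = alignment.members_of(i)
        assert len(members) == len(set(members))  # one-to-one mapping
    for sub in alignment.subgraphs.values():
        assert nx.is_connected(sub)
    assert alignment.size >= params.min_alignment_size
    assert alignment.avg_max_logfold >= params.max_logfold_threshold - 1e-12
    assert 0.0 <= alignment.isc <= 1.0


class TestAlign:
    def test_identical_equal_weight_networks_give_no_alignment(self, fast_params):
        edges = [("A", "B", 0.5), ("B", "C", 0.5), ("C", "D", 0.5)]
        nets = [make_network(f"net{i}", {n: 3.0 for n in "ABCD"}, edges)
                for i in (1, 2)]
        assert tsppi.align(nets, params=fast_params) == []

    def test_fewer_than_two_networks_rejected(self, planted_pair):
        with pytest.raises(ValueError, match="two networks"):
            tsppi.align(planted_pair[:1])

    def test_same_seed_same_result(self, fast_params):
        instance = tsppi.generate(tsppi.SyntheticSpec(n_genes=80, planted_size=5,
                                                      seed=3))
        runs = [tsppi.align(instance.networks, params=fast_params)
                for _ in range(2)]
        key = lambda res: [(a.sort_key(), a.isc, a.avg_max_logfold) for a in res]
        assert key(runs[0]) == key(runs[1])

    def test_outputs_satisfy_structural_invariants(self, fast_params):
        instance = tsppi.generate(tsppi.SyntheticSpec(n_genes=100, planted_size=6,
                                                      n_networks=3, seed=11))
        results = tsppi.align(instance.networks, params=fast_params)
        assert results
        for alignment in results:
            assert_structurally_valid(alignment, fast_params, 3)

    def test_planted_module_is_recalled(self):
        """The top-ranked alignment recovers >= 80% of planted nodes in
        >= 80% of seeded runs."""
        hits = 0
        seeds = range(6)
        for seed in seeds:
            instance = tsppi.generate(
                tsppi.SyntheticSpec(n_genes=150, planted_size=6, n_networks=3,
                                    seed=seed))
            params = AlignmentParameters(attempts=20, seed=seed)
            results = tsppi.align(instance.networks, params=params)
            metrics = tsppi.score_recovery(results, instance)
            if metrics.recall >= 0.8:
                hits += 1
        assert hits >= 0.8 * len(seeds)

    def test_raising_fold_threshold_never_grows_the_top_alignment(self):
        sizes = []
        for threshold in (0.3, 0.6, 1.2):
            per_seed = []
            for seed in range(4):
                instance = tsppi.generate(
                    tsppi.SyntheticSpec(n_genes=100, planted_size=5,
                                        n_networks=2, seed=seed))
                params = AlignmentParameters(
                    attempts=10, seed=seed, max_logfold_threshold=threshold)
                results = tsppi.align(instance.networks, params=params)
                per_seed.append(results[0].size if results else 0)
            sizes.append(np.mean(per_seed))
        assert sizes[0] >= sizes[1] >= sizes[2]
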