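import numpy as np
import pytest

from adam.apf import (BuildParams, KmerPoint, build_forest, build_tree,
                      child_label, forest_stats, partition_node, select_pivot)
from adam.distance import HammingDistance

from helpers import line_points, random_kmer_points


def collect_points(node):
    """All global point indices stored under a node (pivots + leaves)."""
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.extend(int(i) for i in n.leaf_idx)
        else:
            out.extend(int(i) for i in n.pivot_idx)
            stack.extend(c for c in n.children if c is not None)
    return out


def forest_point_multiset(forest):
    out = []
    for t in forest.trees:
        out.extend(collect_points(t.root))
    return out


class TestSelectPivot:
    def setup_method(self):
        # points at distances {1,2,3,4,5} from a base point
        self.points = line_points([1, 2, 3, 4, 5])
        self.prev = KmerPoint("chr1", 99, "+", "a" * 16)  # the base, d=0

    def test_optimal_picks_median_distance(self):
        p = select_pivot(self.points, "optimal", self.prev)
        assert sum(c != "a" for c in p.seq) == 3  # median of {1,2,3,4,5}

    def test_poor_picks_closest(self):
        p = select_pivot(self.points, "poor", self.prev)
        assert sum(c != "a" for c in p.seq) == 1

    def test_random_is_reproducible_with_seed(self):
        a = select_pivot(self.points, "random", rng=np.random.default_rng(5))
        b = select_pivot(self.points, "random", rng=np.random.default_rng(5))
        assert a == b

    def test_empty_set_raises(self):
        import adam.apf as apf

        with pytest.raises(ValueError, match="empty"):
            select_pivot(
                apf.KmerPoints(np.zeros((0, 4), dtype=np.uint8), np.zeros(0),
                               np.zeros(0), np.zeros(0), []), "random")


class TestPartitionNode:
    def test_upper_median_split_tau0(self):
        # base pivot at d=0 plus points at {1,2,8,9}; rng seed 11 selects the
        # base as first pivot, leaving distance multiset {1,2,8,9}
        points = line_points([0, 1, 2, 8, 9])
        params = BuildParams(tau=0, m=0.9, D=1, leaf_size=1, seed=11)
        node, excl = partition_node(points, params,
                                    rng=np.random.default_rng(11))
        assert not node.is_leaf
        assert node.medians.tolist() == [8]  # upper median of {1,2,8,9}
        assert len(excl) == 0
        sizes = sorted(len(c.leaf_idx) for c in node.children if c is not None)
        assert sizes == [2, 2]

    def test_total_exclusion_collapses_to_leaf(self):
        # every non-pivot point at distance 2; tau=2 band [dm-2, dm+2) covers all
        points = line_points([0, 2, 2, 2], k=8)
        # seqs identical for the three d=2 points would be duplicate origins;
        # line_points gives them distinct starts, identical seqs are allowed
        params = BuildParams(tau=2, m=0.0, D=1, leaf_size=1, seed=11)
        node, excl = partition_node(points, params,
                                    rng=np.random.default_rng(11))
        assert node.is_leaf
        assert len(node.leaf_idx) == 4
        assert len(excl) == 0

    def test_two_pivots_give_four_children(self):
        points = random_kmer_points(120, 8, seed=2)
        params = BuildParams(tau=1, m=0.0, D=2, leaf_size=4, seed=0)
        node, excl = partition_node(points, params,
                                    rng=np.random.default_rng(0))
        assert node.d == 2
        assert len(node.children) == 4
        # membership per the bit-label rule, re-derived from raw distances
        fn = HammingDistance()
        for c, child in enumerate(node.children):
            if child is None:
                continue
            for i in child.leaf_idx:
                dists = [fn.batch(points.seqs[i:i + 1],
                                  points.seqs[p])[0]
                         for p in node.pivot_idx]
                assert child_label(dists, node.medians) == c

    def test_all_identical_points_become_leaf(self):
        n = 10
        seqs = np.zeros((n, 8), dtype=np.uint8)
        pts = __import__("adam.apf", fromlist=["KmerPoints"]).KmerPoints(
            seqs, np.zeros(n), np.arange(n), np.zeros(n), ["chr1"])
        node, excl = partition_node(pts, BuildParams(tau=0, m=0.0, D=2,
                                                     leaf_size=1, seed=0))
        assert node.is_leaf and len(node.leaf_idx) == n


class TestChildLabel:
    def test_worked_example_index_13(self):
        # >= median for p3, p2, p0; below for p1 -> digit string 1101
        label = child_label([5, 0, 7, 9], [1, 1, 1, 1])
        assert label == 13
        assert format(label, "04b") == "1101"

    def test_all_below_gives_zero(self):
        assert child_label([0, 1, 2], [5, 5, 5]) == 0

    def test_distance_equal_to_median_goes_high(self):
        assert child_label([4], [4]) == 1

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            child_label([1, 2], [1])


class TestBuildTree:
    def test_small_set_is_single_leaf(self):
        points = random_kmer_points(10, 8, seed=3)
        tree, pool = build_tree(points, BuildParams(leaf_size=32, seed=0))
        assert tree.root.is_leaf
        assert len(pool) == 0
        assert tree.size == 10

    def test_tau0_excludes_nothing(self):
        points = random_kmer_points(200, 8, seed=4)
        tree, pool = build_tree(points, BuildParams(tau=0, m=0.0, D=2,
                                                    leaf_size=8, seed=0))
        assert len(pool) == 0
        assert sorted(collect_points(tree.root)) == list(range(200))

    def test_conservation_with_exclusion(self):
        points = random_kmer_points(200, 8, seed=5)
        tree, pool = build_tree(points, BuildParams(tau=1, m=0.0, D=2,
                                                    leaf_size=8, seed=0))
        stored = collect_points(tree.root)
        assert tree.size == len(stored)
        assert sorted(stored + [int(i) for i in pool]) == list(range(200))


class TestBuildForest:
    def test_tau0_yields_one_tree(self, small_points):
        f = build_forest(small_points, BuildParams(tau=0, m=0.0, D=2,
                                                   leaf_size=8, seed=1))
        assert len(f.trees) == 1

    def test_tree_count_nondecreasing_in_tau(self):
        points = random_kmer_points(1000, 16, seed=42)
        counts = []
        for tau in (0, 1, 2, 4):
            f = build_forest(points, BuildParams(tau=tau, m=0.0, D=1,
                                                 leaf_size=16, seed=3))
            counts.append(len(f.trees))
        assert counts == sorted(counts)
        assert counts[0] == 1

    def test_deterministic_structure_for_fixed_seed(self, small_points):
        def structure(forest):
            out = []
            for t in forest.trees:
                stack = [t.root]
                while stack:
                    n = stack.pop()
                    if n.is_leaf:
                        out.append(("L", tuple(n.leaf_idx.tolist())))
                    else:
                        out.append(("N", tuple(n.pivot_idx.tolist()),
                                    tuple(np.asarray(n.medians).tolist()),
                                    n.tau_node))
                        stack.extend(c for c in n.children if c is not None)
            return out

        params = BuildParams(tau=1, m=0.0, D=2, leaf_size=8, seed=7)
        f1 = build_forest(small_points, params)
        f2 = build_forest(small_points, params)
        assert structure(f1) == structure(f2)

    def test_duplicate_origins_rejected(self):
        import adam.apf as apf

        seqs = np.zeros((2, 8), dtype=np.uint8)
        pts = apf.KmerPoints(seqs, np.zeros(2), np.zeros(2), np.zeros(2),
                             ["chr1"])
        with pytest.raises(ValueError, match="duplicate"):
            build_forest(pts, BuildParams(seed=0))

    def test_identical_seqs_at_distinct_loci_allowed(self):
        import adam.apf as apf

        seqs = np.zeros((5, 8), dtype=np.uint8)
        pts = apf.KmerPoints(seqs, np.zeros(5), np.arange(5), np.zeros(5),
                             ["chr1"])
        f = build_forest(pts, BuildParams(tau=1, m=0.0, leaf_size=2, seed=0))
        assert f.total == 5
        assert sorted(forest_point_multiset(f)) == list(range(5))


class TestForestInvariants:
    @pytest.mark.parametrize("tau,D", [(0, 1), (1, 2), (2, 4)])
    def test_conservation_partition(self, tau, D):
        points = random_kmer_points(400, 8, seed=10 + tau + D)
        f = build_forest(points, BuildParams(tau=tau, m=0.0, D=D,
                                             leaf_size=8, seed=2))
        stored = forest_point_multiset(f)
        assert sorted(stored) == list(range(400))  # no loss, no duplication

    def test_label_soundness_and_band_exclusion(self):
        points = random_kmer_points(300, 8, seed=20)
        f = build_forest(points, BuildParams(tau=1, m=0.0, D=2,
                                             leaf_size=8, seed=2))
        fn = HammingDistance()
        for tree in f.trees:
            stack = [tree.root]
            while stack:
                node = stack.pop()
                if node.is_leaf:
                    continue
                for c, child in enumerate(node.children):
                    if child is None:
                        continue
                    for i in collect_points(child):
                        dists = [int(fn.batch(points.seqs[i:i + 1],
                                              points.seqs[p])[0])
                                 for p in node.pivot_idx]
                        assert child_label(dists, node.medians) == c
                        # stored points must lie outside every pivot's band
                        for dist, dm in zip(dists, node.medians):
                            assert not (dm - node.tau_node <= dist
                                        < dm + node.tau_node)
                    stack.append(child)

    def test_exclusion_fraction_or_max_pivots(self):
        points = random_kmer_points(600, 16, seed=30)
        params = BuildParams(tau=1, m=0.1, D=3, leaf_size=8, seed=4)
        f = build_forest(points, params)
        st = forest_stats(f)
        assert st.node_exclusions  # at least one internal node
        for d, tau, m_node in st.node_exclusions:
            assert m_node <= params.m or d == params.D

    def test_stats_conserve_totals(self, small_points):
        f = build_forest(small_points, BuildParams(tau=1, m=0.0, D=2,
                                                   leaf_size=8, seed=9))
        st = forest_stats(f)
        assert st.pivots + st.leaf_points == st.total == len(small_points)
        assert st.trees == len(f.trees)
        assert sum(st.tree_sizes) == st.total

    def test_auto_tau_respects_m(self):
        points = random_kmer_points(500, 16, seed=31)
        params = BuildParams(tau="auto", m=0.1, D=2, leaf_size=8, seed=4)
        f = build_forest(points, params)
        st = forest_stats(f)
        for d, tau, m_node in st.node_exclusions:
            assert m_node <= params.m
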