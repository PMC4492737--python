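"""Top-k linkage, proximity gating and the agglomeration itself."""

import numpy as np
import pytest
from conftest import (
    assert_same_tree,
    brute_force_tree,
    make_stats,
    random_stats,
)
from hypothesis import given, settings
from hypothesis import strategies as st

from motiontree import (
    ClusterParams,
    InputError,
    build_tree,
    cluster_dissimilarity,
    proximity_ok,
)


def block_stats(values, shape):
    """Stats whose cross block {0..a-1} × {a..a+b-1} holds ``values``."""
    a, b = shape
    n = a + b
    D = np.zeros((n, n))
    D[:a, a:] = np.asarray(values, dtype=float).reshape(a, b)
    D = D + D.T
    M = np.full((n, n), 5.0)
    np.fill_diagonal(M, 0.0)
    return make_stats(D, M)


class TestClusterDissimilarity:
    def test_singleton_pair_is_the_entry(self):
        s = block_stats([[3.7]], (1, 1))
        assert cluster_dissimilarity(s, [0], [1]) == 3.7

    def test_fewer_pairs_than_k_averages_all(self):
        s = block_stats([[5, 4, 3], [2, 1, 0]], (2, 3))
        assert cluster_dissimilarity(s, [0, 1], [2, 3, 4]) == pytest.approx(2.5)

    def test_k_largest_of_25(self):
        s = block_stats(np.arange(1, 26).reshape(5, 5), (5, 5))
        got = cluster_dissimilarity(s, range(5), range(5, 10))
        assert got == pytest.approx(np.mean(np.arange(6, 26)))  # 15.5

    def test_matches_sort_and_average_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b = rng.integers(1, 8, 2)
            vals = rng.normal(0, 3, (a, b)) ** 2
            s = block_stats(vals, (a, b))
            k = int(rng.integers(1, 25))
            got = cluster_dissimilarity(
                s, range(a), range(a, a + b), ClusterParams(k_top=k)
            )
            m = min(k, a * b)
            expect = np.sort(vals.ravel())[::-1][:m].mean()
            assert got == expect

    def test_overlapping_sets_rejected(self):
        s = block_stats([[1.0]], (1, 1))
        with pytest.raises(InputError):
            cluster_dissimilarity(s, [0, 1], [1])


class TestProximity:
    def test_strictly_under_cutoff_passes(self):
        s = make_stats(np.zeros((2, 2)), [[0, 6.9], [6.9, 0]])
        assert proximity_ok(s, [0], [1]) is True

    def test_boundary_is_excluded(self):
        s = make_stats(np.zeros((2, 2)), [[0, 7.0], [7.0, 0]])
        assert proximity_ok(s, [0], [1]) is False

    def test_min_pair_vs_mean_of_pairs_diverge(self):
        # closest cross pair 5 Å, farthest 40 Å: contact exists but the
        # mean distance is far over the cutoff
        M = np.zeros((4, 4))
        M[0, 2], M[0, 3], M[1, 2], M[1, 3] = 5.0, 40.0, 40.0, 40.0
        M = M + M.T
        s = make_stats(np.zeros((4, 4)), M)
        assert proximity_ok(s, [0, 1], [2, 3], ClusterParams()) is True
        assert (
            proximity_ok(
                s, [0, 1], [2, 3], ClusterParams(proximity_rule="mean-of-pairs")
            )
            is False
        )


class TestBuildTree:
    def test_two_residues_single_node(self):
        s = block_stats([[2.5]], (1, 1))
        tree = build_tree(s)
        assert len(tree.nodes) == 1
        assert tree.root.score == 2.5
        assert tree.root.members == (0, 1)

    def test_four_residue_worked_example(self):
        # designed so (0,1) merges, then (2,3), then the two pairs
        D = np.array(
            [
                [0.0, 1.0, 4.0, 5.0],
                [1.0, 0.0, 6.0, 7.0],
                [4.0, 6.0, 0.0, 1.5],
                [5.0, 7.0, 1.5, 0.0],
            ]
        )
        M = np.full((4, 4), 5.0)
        np.fill_diagonal(M, 0.0)
        tree = build_tree(make_stats(D, M))
        steps = [
            ({frozenset(r.left_members), frozenset(r.right_members)}, r.score)
            for r in tree.nodes
        ]
        assert steps[0] == ({frozenset({0}), frozenset({1})}, 1.0)
        assert steps[1] == ({frozenset({2}), frozenset({3})}, 1.5)
        # root linkage: all 4 cross values averaged (fewer than 20 pairs)
        assert steps[2][0] == {frozenset({0, 1}), frozenset({2, 3})}
        assert steps[2][1] == pytest.approx(np.mean([4, 5, 6, 7]))
        # with k_top=2 the root score is the mean of the two largest
        tree2 = build_tree(make_stats(D, M), ClusterParams(k_top=2))
        assert tree2.root.score == pytest.approx(np.mean([7, 6]))

    def test_proximity_deferral_skips_global_minimum(self):
        # (0,1) has the smallest D but sits beyond the cutoff; (0,2)
        # merges first, then {0,2} joins 1 through the in-contact pairs
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        M = np.array([[0.0, 8.0, 5.0], [8.0, 0.0, 5.0], [5.0, 5.0, 0.0]])
        tree = build_tree(make_stats(D, M))
        first = tree.nodes[0]
        assert {frozenset(first.left_members), frozenset(first.right_members)} == {
            frozenset({0}),
            frozenset({2}),
        }
        assert first.score == 2.0
        assert not first.proximity_fallback
        assert tree.root.score == pytest.approx(np.mean([1.0, 3.0]))

    def test_oracle_equivalence_randomized(self):
        rng = np.random.default_rng(1234)
        for trial in range(30):
            proximity = "all-pass" if trial % 2 else "mixed"
            stats = random_stats(rng, proximity=proximity)
            params = ClusterParams(
                k_top=int(rng.integers(1, 25)),
                proximity_rule="min-pair" if trial % 3 else "mean-of-pairs",
            )
            tree = build_tree(stats, params)
            assert_same_tree(tree, brute_force_tree(stats, params))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_structural_invariants(self, seed):
        rng = np.random.default_rng(seed)
        stats = random_stats(rng)
        n = stats.n_atoms
        tree = build_tree(stats)
        assert len(tree.nodes) == n - 1
        assert tree.root.members == tuple(range(n))
        for rec in tree.nodes:
            left, right = set(rec.left_members), set(rec.right_members)
            assert left and right and not (left & right)
            assert rec.score >= 0
            assert len(rec.left_members) >= len(rec.right_members)

    def test_first_merge_is_global_minimum_when_all_pass(self):
        rng = np.random.default_rng(77)
        stats = random_stats(rng, n=10, proximity="all-pass")
        tree = build_tree(stats, ClusterParams(k_top=1))
        i, j = tree.nodes[0].left_members[0], tree.nodes[0].right_members[0]
        off = stats.D + np.diag(np.full(10, np.inf))
        assert stats.D[i, j] == off.min()

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(5)
        stats = random_stats(rng, n=11)
        t1 = build_tree(stats)
        t2 = build_tree(stats)
        for a, b in zip(t1.nodes, t2.nodes):
            assert a == b

    def test_ties_break_toward_smallest_leaf_indices(self):
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0.0)
        M = np.full((4, 4), 5.0)
        np.fill_diagonal(M, 0.0)
        tree = build_tree(make_stats(D, M))
        first = tree.nodes[0]
        assert set(first.members) == {0, 1}

    def test_disconnected_selection_falls_back_with_flag(self, caplog):
        # no pair is ever in contact: merges proceed, every node flagged
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        M = np.array([[0.0, 30.0], [30.0, 0.0]])
        import logging

        logging.getLogger("motiontree.clustering").setLevel(logging.WARNING)
        with caplog.at_level("WARNING", logger="motiontree.clustering"):
            tree = build_tree(make_stats(D, M))
        assert tree.root.proximity_fallback
        assert "proximity" in caplog.text

    def test_single_residue_rejected(self):
        with pytest.raises(InputError):
            build_tree(make_stats(np.zeros((1, 1)), np.zeros((1, 1))))

    def test_bad_params_rejected(self):
        with pytest.raises(InputError):
            ClusterParams(k_top=0)
        with pytest.raises(InputError):
            ClusterParams(proximity_cutoff=0.0)
        with pytest.raises(InputError):
            ClusterParams(proximity_rule="nearest")
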