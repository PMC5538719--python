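"""Modularity, Louvain partitions, and module-based nodal roles."""

import numpy as np
import pytest

import oracles
from braingraph.community import (
    Partition,
    match_modules,
    modularity_partition,
    modularity_Q,
    module_average_degree,
    participation_coefficient,
    within_module_zscore,
)
from braingraph.exceptions import UndefinedMeasureError
from braingraph.graph import Graph


def bu(A):
    return Graph(adjacency=np.asarray(A, dtype=float), weighted=False, directed=False)


def two_triangles():
    A = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                if i != j:
                    A[i, j] = 1.0
    return A


class TestModularityQ:
    def test_all_in_one_module_is_zero(self, rng):
        A = oracles.random_binary_graph(rng, 6, 0.5)
        assert modularity_Q(bu(A), np.ones(6, dtype=int)) == pytest.approx(0.0, abs=1e-15)

    def test_two_disconnected_triangles_true_split(self):
        # e_11 = e_22 = 1/2, a_1 = a_2 = 1/2 -> Q = 2*(1/2 - 1/4) = 1/2
        A = two_triangles()
        assignment = np.array([1, 1, 1, 2, 2, 2])
        assert modularity_Q(bu(A), assignment) == pytest.approx(0.5)

    def test_random_assignment_matches_hand_summed_oracle(self, rng):
        for _ in range(20):
            A = oracles.random_weighted_graph(rng, 7, 0.5)
            if A.sum() == 0:
                continue
            assignment = rng.integers(1, 4, size=7)
            g = Graph(adjacency=A, weighted=True, directed=False)
            assert modularity_Q(g, assignment) == pytest.approx(
                oracles.modularity_Q(A, assignment), abs=1e-12
            )


class TestModularityPartition:
    def test_two_triangles_recovered_with_optimal_Q(self):
        part = modularity_partition(bu(two_triangles()), seed=0)
        assert part.n_modules == 2
        assert len(set(part.assignment[:3])) == 1
        assert len(set(part.assignment[3:])) == 1
        assert part.Q == pytest.approx(0.5)
        # exhaustive search confirms 0.5 is the optimum
        assert oracles.best_partition_Q(two_triangles()) == pytest.approx(0.5)

    def test_complete_graph_single_module_optimal(self):
        A = 1.0 - np.eye(5)
        part = modularity_partition(bu(A), seed=0)
        assert part.Q == pytest.approx(oracles.best_partition_Q(A), abs=1e-12)
        assert part.Q == pytest.approx(0.0, abs=1e-12)

    def test_reported_Q_is_self_consistent(self, rng):
        A = oracles.random_binary_graph(rng, 8, 0.4)
        if A.sum() == 0:
            A[0, 1] = A[1, 0] = 1.0
        part = modularity_partition(bu(A), seed=3)
        assert part.Q == pytest.approx(modularity_Q(bu(A), part.assignment), abs=1e-15)

    def test_near_optimal_on_small_graphs(self):
        # Louvain Q within 5% of the exhaustive-search optimum
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(100):
            n = int(rng.integers(4, 8))
            A = oracles.random_binary_graph(rng, n, float(rng.uniform(0.3, 0.7)))
            if A.sum() == 0:
                continue
            part = modularity_partition(bu(A), seed=0)
            best = oracles.best_partition_Q(A)
            assert part.Q >= 0.95 * best - 1e-12 if best > 0 else part.Q >= best - 1e-12
            checked += 1
        assert checked >= 90

    def test_seeded_runs_bit_reproducible(self, rng):
        A = oracles.random_binary_graph(rng, 12, 0.3)
        p1 = modularity_partition(bu(A), seed=42)
        p2 = modularity_partition(bu(A), seed=42)
        np.testing.assert_array_equal(p1.assignment, p2.assignment)
        assert p1.Q == p2.Q

    def test_edgeless_graph_rejected(self):
        with pytest.raises(UndefinedMeasureError):
            modularity_partition(bu(np.zeros((4, 4))), seed=0)


class TestNodalRoles:
    def test_complete_graph_one_module_all_z_zero(self):
        A = 1.0 - np.eye(4)
        part = Partition(assignment=np.ones(4, dtype=int), Q=0.0)
        np.testing.assert_allclose(within_module_zscore(bu(A), part), 0.0)

    def test_high_within_degree_node_positive_z(self):
        # module {0,1,2,3}: node 0 connected to all, others only to 0
        A = np.zeros((4, 4))
        A[0, 1:] = A[1:, 0] = 1.0
        part = Partition(assignment=np.ones(4, dtype=int), Q=0.0)
        z = within_module_zscore(bu(A), part)
        kappa = np.array([3.0, 1.0, 1.0, 1.0])
        expected = (kappa - kappa.mean()) / kappa.std()
        np.testing.assert_allclose(z, expected)
        assert z[0] > 0

    def test_singleton_module_z_zero(self):
        A = two_triangles()
        assignment = np.array([1, 1, 1, 2, 2, 3])  # node 5 singleton, but disconnected triangles
        A[3, 5] = A[5, 3] = 1.0  # keep node 5 connected
        part = Partition(assignment=assignment, Q=modularity_Q(bu(A), assignment))
        assert within_module_zscore(bu(A), part)[5] == 0.0

    def test_participation_zero_inside_own_module(self):
        A = two_triangles()
        part = Partition(assignment=np.array([1, 1, 1, 2, 2, 2]), Q=0.5)
        np.testing.assert_allclose(participation_coefficient(bu(A), part), 0.0)

    def test_participation_half_for_even_split(self):
        # degree-4 node 0 with 2 edges in module 1, 2 in module 2
        A = np.zeros((5, 5))
        A[0, 1:] = A[1:, 0] = 1.0
        part = Partition(assignment=np.array([1, 1, 1, 2, 2]), Q=0.0)
        p = participation_coefficient(bu(A), part)
        assert p[0] == pytest.approx(0.5)  # 1 - 2*(2/4)^2

    def test_isolated_node_participation_zero_and_bounds(self, rng):
        A = oracles.random_binary_graph(rng, 8, 0.4)
        A[7, :] = A[:, 7] = 0.0
        if A.sum() == 0:
            A[0, 1] = A[1, 0] = 1.0
        assignment = rng.integers(1, 4, size=8)
        assignment = np.unique(assignment, return_inverse=True)[1] + 1
        part = Partition(assignment=assignment, Q=modularity_Q(bu(A), assignment))
        p = participation_coefficient(bu(A), part)
        assert p[7] == 0.0
        assert np.all((p >= 0.0) & (p <= 1.0))

    def test_zscore_mean_zero_within_modules(self, rng):
        A = oracles.random_binary_graph(rng, 10, 0.5)
        assignment = np.array([1] * 5 + [2] * 5)
        part = Partition(assignment=assignment, Q=modularity_Q(bu(A), assignment))
        z = within_module_zscore(bu(A), part)
        for mid in (1, 2):
            members = part.members(mid)
            kappa_sd = np.std((A[np.ix_(members, members)] != 0).sum(axis=1))
            if kappa_sd > 0:
                assert np.mean(z[members]) == pytest.approx(0.0, abs=1e-12)


class TestModuleAverageDegree:
    def test_whole_complete_graph(self):
        A = 1.0 - np.eye(4)
        part = Partition(assignment=np.ones(4, dtype=int), Q=0.0)
        assert module_average_degree(bu(A), part, 1) == 3.0

    def test_singleton_isolated_module(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        part = Partition(assignment=np.array([1, 1, 2]), Q=0.0)
        assert module_average_degree(bu(A), part, 2) == 0.0

    def test_matches_per_node_mean_oracle(self, rng):
        A = oracles.random_weighted_graph(rng, 9, 0.5)
        g = Graph(adjacency=A, weighted=True, directed=False)
        assignment = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        part = Partition(assignment=assignment, Q=0.0)
        for mid in (1, 2, 3):
            members = np.flatnonzero(assignment == mid)
            expected = np.mean([A[v].sum() for v in members])  # strength on weighted graph
            assert module_average_degree(g, part, mid) == pytest.approx(expected)


class TestMatchModules:
    def test_identical_partitions_map_identity(self):
        p = Partition(assignment=np.array([1, 1, 2, 2, 3, 3]), Q=0.0)
        assert match_modules(p, p) == {1: 1, 2: 2, 3: 3}

    def test_relabelled_partition_maps_by_overlap(self):
        ref = Partition(assignment=np.array([1, 1, 1, 2, 2, 2]), Q=0.0)
        other = Partition(assignment=np.array([2, 2, 2, 1, 1, 1]), Q=0.0)
        assert match_modules(ref, other) == {2: 1, 1: 2}
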