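"""Graph measures against closed forms and brute-force oracles."""

import numpy as np
import pytest

import oracles
from braingraph.exceptions import UndefinedMeasureError, ValidationError
from braingraph.graph import Graph
from braingraph.measures import (
    betweenness,
    char_path_length,
    closeness,
    clustering,
    degree,
    distances,
    global_efficiency,
    local_efficiency,
    small_worldness,
    strength,
    transitivity,
)
from braingraph.nullmodels import random_ensemble


def bu(A):
    return Graph(adjacency=np.asarray(A, dtype=float), weighted=False, directed=False)


def wu(A):
    return Graph(adjacency=np.asarray(A, dtype=float), weighted=True, directed=False)


def complete(n):
    return 1.0 - np.eye(n)


def ring(n):
    A = np.zeros((n, n))
    for i in range(n):
        A[i, (i + 1) % n] = A[(i + 1) % n, i] = 1.0
    return A


def star(n_leaves):
    A = np.zeros((n_leaves + 1, n_leaves + 1))
    A[0, 1:] = A[1:, 0] = 1.0
    return A


def path3():
    A = np.zeros((3, 3))
    A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1.0
    return A


class TestClosedForms:
    def test_complete_graph_has_unit_everything(self):
        g = bu(complete(4))
        assert char_path_length(g).values == 1.0
        np.testing.assert_allclose(clustering(g).values, 1.0)
        assert transitivity(g).values == 1.0
        np.testing.assert_allclose(betweenness(g).values, 0.0)
        np.testing.assert_allclose(global_efficiency(g).values, 1.0)
        np.testing.assert_allclose(local_efficiency(g).values, 1.0)
        np.testing.assert_allclose(closeness(g).values, 1.0)

    def test_degree_of_star_and_complete(self):
        np.testing.assert_array_equal(degree(bu(complete(4))), [3, 3, 3, 3])
        np.testing.assert_array_equal(degree(bu(star(4))), [4, 1, 1, 1, 1])

    def test_star_center_local_efficiency_and_transitivity_zero(self):
        g = bu(star(4))
        assert local_efficiency(g).values[0] == 0.0
        assert transitivity(g).values == 0.0

    def test_ring_of_five_char_path_length(self):
        # each node sees distances 1,1,2,2 -> nodal mean 1.5
        assert char_path_length(bu(ring(5))).values == pytest.approx(1.5)

    def test_ring_of_five_global_efficiency(self):
        # per node: mean of (1, 1, 1/2, 1/2) = 0.75
        np.testing.assert_allclose(global_efficiency(bu(ring(5))).values, 0.75)

    def test_path_distances_closeness_betweenness(self):
        g = bu(path3())
        D = distances(g)
        assert D[0, 2] == 2.0
        c = closeness(g).values
        assert c[1] == pytest.approx(1.0)
        assert c[0] == pytest.approx(1 / 1.5)
        b = betweenness(g, normalized=False).values
        np.testing.assert_allclose(b, [0.0, 1.0, 0.0])
        assert betweenness(g).values[1] == pytest.approx(1.0)

    def test_weighted_edge_length_is_reciprocal_weight(self):
        A = np.zeros((2, 2))
        A[0, 1] = A[1, 0] = 0.5
        assert distances(wu(A))[0, 1] == pytest.approx(2.0)

    def test_triangle_strength(self):
        A = 0.5 * (1 - np.eye(3))
        np.testing.assert_allclose(strength(wu(A)), 1.0)

    def test_disconnected_pairs_excluded_from_path_length(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1.0
        assert char_path_length(bu(A)).values == 1.0

    def test_isolated_node_closeness_zero_and_edgeless_cpl_undefined(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        assert closeness(bu(A)).values[2] == 0.0
        with pytest.raises(UndefinedMeasureError):
            char_path_length(bu(np.zeros((3, 3))))

    def test_directed_graph_rejected(self):
        g = Graph(adjacency=np.array([[0.0, 1.0], [0.0, 0.0]]), weighted=True, directed=True)
        with pytest.raises(ValidationError):
            degree(g)


def _random_graphs(n_graphs):
    rng = np.random.default_rng(1234)
    for i in range(n_graphs):
        n = int(rng.integers(4, 9))
        p = float(rng.uniform(0.25, 0.8))
        if i % 2 == 0:
            yield oracles.random_binary_graph(rng, n, p), False
        else:
            yield oracles.random_weighted_graph(rng, n, p), True


class TestOracleEquivalence:
    """Every measure equals a brute-force oracle on >= 200 small random graphs."""

    N_GRAPHS = 200

    def test_all_measures_match_brute_force(self):
        for A, weighted in _random_graphs(self.N_GRAPHS):
            g = wu(A) if weighted else bu(A)
            tol = dict(atol=1e-12, rtol=0) if weighted else dict(atol=0, rtol=0)

            np.testing.assert_array_equal(degree(g), (A != 0).sum(axis=1))
            if weighted:
                np.testing.assert_allclose(strength(g), A.sum(axis=1), **tol)

            D = distances(g)
            D_oracle = oracles.floyd_warshall(A, weighted)
            np.testing.assert_allclose(D, D_oracle, atol=1e-12, rtol=0)

            pl = oracles.nodal_path_length(D_oracle)
            if not np.all(np.isnan(pl)):
                assert char_path_length(g).values == pytest.approx(
                    np.nanmean(pl), abs=1e-12
                )
            np.testing.assert_allclose(closeness(g).values, oracles.closeness(D_oracle), atol=1e-12)
            np.testing.assert_allclose(
                global_efficiency(g).values, oracles.nodal_efficiency(D_oracle), atol=1e-12
            )
            np.testing.assert_allclose(
                local_efficiency(g).values, oracles.local_efficiency(A, weighted), atol=1e-12
            )
            np.testing.assert_allclose(
                betweenness(g).values, oracles.betweenness(A, weighted), atol=1e-9
            )
            np.testing.assert_allclose(
                clustering(g).values, oracles.clustering(A, weighted), atol=1e-12
            )
            assert transitivity(g).values == pytest.approx(
                oracles.transitivity(A, weighted), abs=1e-12
            )

    def test_node_relabeling_equivariance(self, rng):
        A = oracles.random_weighted_graph(rng, 7, 0.6)
        perm = rng.permutation(7)
        P = np.eye(7)[perm]
        Ap = P @ A @ P.T
        g, gp = wu(A), wu(Ap)
        for fn in (closeness, global_efficiency, local_efficiency, clustering, betweenness):
            np.testing.assert_allclose(
                np.asarray(fn(gp).values), np.asarray(fn(g).values)[perm], atol=1e-9
            )
        assert char_path_length(gp).values == pytest.approx(char_path_length(g).values)
        assert transitivity(gp).values == pytest.approx(transitivity(g).values)

    def test_strength_equals_degree_on_binary_weights(self, rng):
        A = oracles.random_binary_graph(rng, 8, 0.5)
        np.testing.assert_array_equal(strength(wu(A)), degree(bu(A)))

    def test_clustering_mean_equals_transitivity_on_regular_graph(self):
        g = bu(ring(8))
        assert np.mean(clustering(g).values) == pytest.approx(float(transitivity(g).values))
        k = bu(complete(6))
        assert np.mean(clustering(k).values) == pytest.approx(float(transitivity(k).values))


class TestSmallWorldness:
    def ws_lattice(self, n=20, k=4):
        A = np.zeros((n, n))
        for i in range(n):
            for d in range(1, k // 2 + 1):
                j = (i + d) % n
                A[i, j] = A[j, i] = 1.0
        return A

    def test_self_ensemble_gives_exactly_one(self):
        g = bu(self.ws_lattice())
        assert small_worldness(g, [g, g, g]).values == pytest.approx(1.0)

    def test_rewired_lattice_is_small_world(self):
        # 10% rewired ring lattice vs degree-matched ensembles: sigma > 1
        rng = np.random.default_rng(7)
        sigmas = []
        for rep in range(20):
            A = self.ws_lattice()
            edges = np.argwhere(np.triu(A, 1))
            for e in rng.choice(len(edges), size=4, replace=False):  # ~10% of 40 edges
                i, j = edges[e]
                A[i, j] = A[j, i] = 0.0
                while True:
                    a, b = rng.integers(0, 20, 2)
                    if a != b and A[a, b] == 0:
                        A[a, b] = A[b, a] = 1.0
                        break
            g = bu(A)
            ens = random_ensemble(g, 8, seed=rep)
            sigmas.append(float(small_worldness(g, ens).values))
        assert np.mean(sigmas) > 1.0
        assert np.quantile(sigmas, 0.1) > 1.0

    def test_random_graph_sigma_near_one(self):
        rng = np.random.default_rng(11)
        A = oracles.random_binary_graph(rng, 24, 0.3)
        g = bu(A)
        ens = random_ensemble(g, 50, seed=3)
        sigma = float(small_worldness(g, ens).values)
        assert abs(sigma - 1.0) < 0.2
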