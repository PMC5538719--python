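"""Degree-preserving random graphs and measure normalisation.

Observed network measures are only interpretable against a null: a random
graph with the same degree sequence (and, for weighted graphs, the same
weight distribution). Binary graphs are randomised by Maslov-Sneppen
pairwise edge rewiring, which preserves every node's degree exactly;
weighted graphs rewire the topology the same way and then reassign the
original multiset of weights to the new edges at random, preserving the
weight distribution exactly (node strengths are free to change).

``normalized_measure`` divides an observed global measure by its mean over
an ensemble of such nulls — the normalisation behind small-worldness-style
statistics.
"""

from __future__ import annotations

from typing import Callable, Sequence, Union

import numpy as np

from .exceptions import UndefinedMeasureError, ValidationError
from .graph import Graph
from .measures import GLOBAL_MEASURES

__all__ = ["randomize_binary", "randomize_weighted", "random_ensemble", "normalized_measure"]

# Per-swap retry budget: after 10x the requested number of successful swaps
# in failed proposals, remaining swaps are skipped (dense or tiny graphs may
# admit few valid rewirings).
_RETRY_FACTOR = 10


def _edge_list(A: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(np.triu(A, k=1))
    return np.column_stack([rows, cols])


def _rewire(
    A_bin: np.ndarray, iter_per_edge: int, rng: np.random.Generator
) -> np.ndarray:
    """Maslov-Sneppen rewiring of a binary symmetric adjacency; returns new adjacency."""
    R = A_bin.shape[0]
    edges = _edge_list(A_bin)
    m = edges.shape[0]
    if m < 2:
        return A_bin.copy()
    A = A_bin.copy()
    target = iter_per_edge * m
    budget = _RETRY_FACTOR * target
    swaps = 0
    attempts = 0
    while swaps < target and attempts < budget:
        attempts += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b or a == c or b == d:
            continue
        if A[a, d] or A[c, b]:
            continue
        A[a, b] = A[b, a] = 0
        A[c, d] = A[d, c] = 0
        A[a, d] = A[d, a] = 1
        A[c, b] = A[b, c] = 1
        edges[i] = sorted((a, d))
        edges[j] = sorted((c, b))
        swaps += 1
    return A


def randomize_binary(g: Graph, iter_per_edge: int = 10, seed: int = 0) -> Graph:
    """Degree-preserving randomisation of a binary undirected graph.

    Performs ``iter_per_edge`` successful pairwise rewirings per edge; no
    self-loops or duplicate edges are ever introduced, so the degree
    sequence of the output equals the input's exactly. Graphs admitting no
    valid swap come back as copies.
    """
    if g.weighted or g.directed:
        raise ValidationError("randomize_binary expects a binary undirected graph")
    rng = np.random.default_rng(seed)
    A = _rewire(g.adjacency, iter_per_edge, rng)
    return Graph(adjacency=A, weighted=False, directed=False, param=g.param, labels=g.labels)


def randomize_weighted(g: Graph, iter_per_edge: int = 10, seed: int = 0) -> Graph:
    """Degree- and weight-distribution-preserving randomisation of a WU graph.

    The binary topology is rewired as in :func:`randomize_binary`, then the
    original multiset of edge weights is assigned to the new edge set in
    random order. Degrees and the weight distribution are preserved exactly;
    node strengths are not (they vary under the null, as intended).
    """
    if not g.weighted or g.directed:
        raise ValidationError("randomize_weighted expects a weighted undirected graph")
    rng = np.random.default_rng(seed)
    A = g.adjacency
    B = _rewire((A != 0).astype(float), iter_per_edge, rng)
    weights = A[np.nonzero(np.triu(A != 0, k=1))]
    new_edges = _edge_list(B)
    perm = rng.permutation(weights.size)
    W = np.zeros_like(A)
    W[new_edges[:, 0], new_edges[:, 1]] = weights[perm]
    W += W.T
    return Graph(adjacency=W, weighted=True, directed=False, param=g.param, labels=g.labels)


def random_ensemble(
    g: Graph, n_random: int, seed: int = 0, iter_per_edge: int = 10
) -> list[Graph]:
    """Ensemble of independent degree-matched randomisations of ``g``."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_random)
    fn = randomize_weighted if g.weighted else randomize_binary
    return [fn(g, iter_per_edge=iter_per_edge, seed=int(s)) for s in seeds]


def normalized_measure(
    g: Graph,
    measure: Union[str, Callable[[Graph], float]],
    n_random: int = 100,
    seed: int = 0,
    iter_per_edge: int = 10,
    ensemble: Sequence[Graph] | None = None,
) -> float:
    """Observed global measure divided by its mean over a random ensemble.

    ``measure`` is a registry name from :data:`~braingraph.measures.GLOBAL_MEASURES`
    or any callable Graph -> float.
    """
    fn = GLOBAL_MEASURES[measure] if isinstance(measure, str) else measure
    if ensemble is None:
        ensemble = random_ensemble(g, n_random, seed=seed, iter_per_edge=iter_per_edge)
    vals = [fn(r) for r in ensemble]
    mean = float(np.mean(vals))
    if mean == 0:
        raise UndefinedMeasureError("normalisation undefined: ensemble mean is zero")
    return float(fn(g) / mean)
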