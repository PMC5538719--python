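"""Global and nodal graph-theory measures on binary and weighted undirected graphs.

Implemented measures: degree, strength, all-pairs shortest-path distances,
characteristic path length, closeness centrality, betweenness centrality
(Brandes), global and local efficiency, clustering coefficient, transitivity
and small-worldness. Nodal measures return a length-R vector; global ones a
scalar (usually the mean of the nodal vector).

Conventions on weighted graphs: a stronger connection means a *shorter*
distance, so edge length is the reciprocal of the edge weight (1/w);
degree counts nonzero edges regardless of weight; clustering uses the
Onnela geometric-mean formulation with weights normalised by the maximum
weight. Disconnected graphs: infinite distances are excluded from the
nodal means of path length and closeness (an isolated node gets closeness
0), while the efficiency measures absorb them naturally as 1/inf = 0.

Transitivity is the global triangle-closure ratio 3*triangles / #2-paths,
bounded in [0, 1]; small-worldness is sigma = (C/C_rand) / (L/L_rand)
against an ensemble of degree-matched random graphs, with sigma > 1
indicating small-world architecture.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence, Union

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .exceptions import UndefinedMeasureError, ValidationError
from .graph import Graph

__all__ = [
    "MeasureResult",
    "degree",
    "strength",
    "distances",
    "char_path_length",
    "closeness",
    "betweenness",
    "global_efficiency",
    "local_efficiency",
    "clustering",
    "transitivity",
    "small_worldness",
    "GLOBAL_MEASURES",
    "NODAL_MEASURES",
    "measures_table",
]


@dataclass(frozen=True)
class MeasureResult:
    """A named measure value: a global scalar or a nodal length-R vector."""

    name: str
    scope: Literal["global", "nodal"]
    values: Union[float, np.ndarray]
    param: object = None  # GraphParam of the graph it was computed on

    def __post_init__(self) -> None:
        if self.scope == "nodal":
            v = np.asarray(self.values, dtype=float)
            object.__setattr__(self, "values", v)
            if v.ndim != 1:
                raise ValidationError("nodal measure values must be a vector")


def _require_undirected(g: Graph) -> np.ndarray:
    if g.directed:
        raise ValidationError("measures are implemented for undirected graphs")
    return g.adjacency


def degree(g: Graph) -> np.ndarray:
    """Number of connections of each node (nonzero incident edges)."""
    A = _require_undirected(g)
    return (A != 0).sum(axis=1).astype(float)


def strength(g: Graph) -> np.ndarray:
    """Sum of the weights of each node's connections."""
    A = _require_undirected(g)
    return A.sum(axis=1)


def _length_matrix(g: Graph) -> np.ndarray:
    """Edge lengths: 1 for binary edges, 1/w for weighted; 0 marks no edge."""
    A = _require_undirected(g)
    if np.any(A < 0):
        raise ValidationError("distances require nonnegative weights (apply abs/zero rule first)")
    if g.weighted:
        with np.errstate(divide="ignore"):
            L = np.where(A > 0, 1.0 / np.where(A > 0, A, 1.0), 0.0)
        return L
    return (A != 0).astype(float)


def distances(g: Graph) -> np.ndarray:
    """All-pairs shortest-path distance matrix; +inf for unreachable pairs.

    Breadth-first semantics on binary graphs, Dijkstra on 1/w lengths for
    weighted graphs.
    """
    L = _length_matrix(g)
    if not g.weighted:
        D = _csgraph_shortest_path(L, method="D", directed=False, unweighted=True)
    else:
        D = _csgraph_shortest_path(L, method="D", directed=False)
    np.fill_diagonal(D, 0.0)
    return D


def _nodal_path_length(D: np.ndarray) -> np.ndarray:
    """Mean finite off-diagonal distance per node; NaN for isolated nodes."""
    R = D.shape[0]
    off = D.copy()
    np.fill_diagonal(off, np.inf)  # exclude self-distance
    finite = np.isfinite(off)
    counts = finite.sum(axis=1)
    sums = np.where(finite, off, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def char_path_length(g: Graph) -> MeasureResult:
    """Characteristic path length: mean shortest distance to reachable nodes.

    The global value averages the nodal values over nodes that reach at
    least one other node; a completely edgeless graph has no defined value.
    """
    D = distances(g)
    nodal = _nodal_path_length(D)
    if np.all(np.isnan(nodal)):
        raise UndefinedMeasureError("characteristic path length undefined on an edgeless graph")
    return MeasureResult("char_path_length", "global", float(np.nanmean(nodal)), g.param)


def char_path_length_nodal(g: Graph) -> MeasureResult:
    D = distances(g)
    return MeasureResult("path_length", "nodal", _nodal_path_length(D), g.param)


def closeness(g: Graph) -> MeasureResult:
    """Closeness centrality: reciprocal of a node's mean finite distance; 0 if isolated."""
    D = distances(g)
    nodal = _nodal_path_length(D)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(np.isnan(nodal) | (nodal == 0), 0.0, 1.0 / nodal)
    return MeasureResult("closeness", "nodal", c, g.param)


def betweenness(g: Graph, normalized: bool = True) -> MeasureResult:
    """Betweenness centrality: fraction of all shortest paths through a node.

    Brandes' accumulation over single-source shortest paths; weighted graphs
    count paths under 1/w lengths. ``normalized`` divides the raw per-node
    value by the (R-1)(R-2)/2 node pairs it could mediate.
    """
    L = _length_matrix(g)
    R = L.shape[0]
    bc = np.zeros(R)
    neighbors: list[np.ndarray] = [np.flatnonzero(L[i]) for i in range(R)]

    for s in range(R):
        # single-source shortest paths with path counting
        sigma = np.zeros(R)
        sigma[s] = 1.0
        dist = np.full(R, np.inf)
        dist[s] = 0.0
        preds: list[list[int]] = [[] for _ in range(R)]
        order: list[int] = []
        if not g.weighted:
            queue = [s]
            head = 0
            while head < len(queue):
                v = queue[head]
                head += 1
                order.append(v)
                for w in neighbors[v]:
                    if np.isinf(dist[w]):
                        dist[w] = dist[v] + 1
                        queue.append(int(w))
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
        else:
            done = np.zeros(R, dtype=bool)
            heap: list[tuple[float, int]] = [(0.0, s)]
            while heap:
                dv, v = heapq.heappop(heap)
                if done[v]:
                    continue
                done[v] = True
                order.append(v)
                for w in neighbors[v]:
                    alt = dv + L[v, w]
                    if alt < dist[w] - 1e-15 * max(1.0, abs(alt)):
                        dist[w] = alt
                        sigma[w] = sigma[v]
                        preds[w] = [v]
                        heapq.heappush(heap, (alt, int(w)))
                    elif not done[w] and abs(alt - dist[w]) <= 1e-12 * max(1.0, abs(alt)):
                        sigma[w] += sigma[v]
                        preds[w].append(v)
        delta = np.zeros(R)
        for v in reversed(order):
            for p in preds[v]:
                delta[p] += sigma[p] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]

    bc /= 2.0  # each unordered pair counted from both endpoints
    if normalized:
        pairs = (R - 1) * (R - 2) / 2.0
        if pairs > 0:
            bc = bc / pairs
    return MeasureResult("betweenness", "nodal", bc, g.param)


def _efficiency_from_distances(D: np.ndarray) -> np.ndarray:
    R = D.shape[0]
    with np.errstate(divide="ignore"):
        inv = np.where(D > 0, 1.0 / D, 0.0)
    np.fill_diagonal(inv, 0.0)
    if R < 2:
        return np.zeros(R)
    return inv.sum(axis=1) / (R - 1)


def global_efficiency(g: Graph) -> MeasureResult:
    """Nodal efficiency: mean inverse shortest distance to every other node."""
    D = distances(g)
    return MeasureResult("global_efficiency", "nodal", _efficiency_from_distances(D), g.param)


def local_efficiency(g: Graph) -> MeasureResult:
    """Global efficiency of each node's neighbor subgraph (node excluded).

    Nodes with fewer than two neighbors score 0.
    """
    A = _require_undirected(g)
    R = A.shape[0]
    vals = np.zeros(R)
    for v in range(R):
        nbrs = np.flatnonzero(A[v] != 0)
        if nbrs.size < 2:
            continue
        sub = Graph(
            adjacency=A[np.ix_(nbrs, nbrs)], weighted=g.weighted, directed=False
        )
        vals[v] = float(np.mean(global_efficiency(sub).values))
    return MeasureResult("local_efficiency", "nodal", vals, g.param)


def clustering(g: Graph) -> MeasureResult:
    """Clustering coefficient: fraction of a node's neighbor pairs that are connected.

    Binary: 2 * triangles(v) / (k_v (k_v - 1)). Weighted: Onnela variant —
    triangle intensity as the geometric mean of its three weights after
    normalising all weights by the maximum weight.
    """
    A = _require_undirected(g)
    k = (A != 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    if g.weighted:
        wmax = A.max()
        W = np.cbrt(A / wmax) if wmax > 0 else A
        tri = np.diag(W @ W @ W)
    else:
        tri = np.diag(A @ A @ A)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return MeasureResult("clustering", "nodal", c, g.param)


def transitivity(g: Graph) -> MeasureResult:
    """Global triangle-closure ratio: 3 * triangles / paths of length two.

    On weighted graphs, triangle intensity follows the same Onnela weighting
    as :func:`clustering`. Returns 0 when the graph has no 2-paths.
    """
    A = _require_undirected(g)
    k = (A != 0).sum(axis=1).astype(float)
    paths2 = float((k * (k - 1)).sum())
    if paths2 == 0:
        return MeasureResult("transitivity", "global", 0.0, g.param)
    if g.weighted:
        wmax = A.max()
        W = np.cbrt(A / wmax) if wmax > 0 else A
        closed = float(np.trace(W @ W @ W))
    else:
        closed = float(np.trace(A @ A @ A))
    return MeasureResult("transitivity", "global", closed / paths2, g.param)


def small_worldness(g: Graph, ensemble: Sequence[Graph]) -> MeasureResult:
    """Small-world index sigma = (C / <C_rand>) / (L / <L_rand>).

    ``ensemble`` is a collection of random graphs from the same degree/
    density family (see :mod:`braingraph.nullmodels`). sigma > 1 indicates a
    network with near-random path length but excess clustering.
    """
    if not ensemble:
        raise ValidationError("need a nonempty random-graph ensemble")
    C = float(np.mean(clustering(g).values))
    L = float(char_path_length(g).values)
    C_rand = float(np.mean([np.mean(clustering(r).values) for r in ensemble]))
    L_rand = float(np.mean([char_path_length(r).values for r in ensemble]))
    if C_rand == 0 or L_rand == 0:
        raise UndefinedMeasureError("small-worldness undefined: degenerate random ensemble")
    if C == 0 or L == 0:
        raise UndefinedMeasureError("small-worldness undefined: zero clustering or path length")
    sigma = (C / C_rand) / (L / L_rand)
    return MeasureResult("small_worldness", "global", sigma, g.param)


# Registries used by the workflow layer and the null-model normalizer.
GLOBAL_MEASURES: dict[str, Callable[[Graph], float]] = {
    "char_path_length": lambda g: float(char_path_length(g).values),
    "global_efficiency": lambda g: float(np.mean(global_efficiency(g).values)),
    "local_efficiency": lambda g: float(np.mean(local_efficiency(g).values)),
    "clustering": lambda g: float(np.mean(clustering(g).values)),
    "transitivity": lambda g: float(transitivity(g).values),
    "mean_degree": lambda g: float(np.mean(degree(g))),
    "mean_strength": lambda g: float(np.mean(strength(g))),
}

NODAL_MEASURES: dict[str, Callable[[Graph], np.ndarray]] = {
    "degree": lambda g: degree(g),
    "strength": lambda g: strength(g),
    "path_length": lambda g: np.asarray(char_path_length_nodal(g).values),
    "closeness": lambda g: np.asarray(closeness(g).values),
    "betweenness": lambda g: np.asarray(betweenness(g).values),
    "global_efficiency": lambda g: np.asarray(global_efficiency(g).values),
    "local_efficiency": lambda g: np.asarray(local_efficiency(g).values),
    "clustering": lambda g: np.asarray(clustering(g).values),
}


def measures_table(
    graphs: Iterable[Graph],
    graph_ids: Iterable[str],
    global_names: Sequence[str] = ("char_path_length", "clustering", "transitivity"),
    nodal_names: Sequence[str] = ("degree",),
):
    """Long-form table of measures over a family of graphs.

    Columns: graph id, param kind, param value, measure, scope,
    node label (or GLOBAL), value.
    """
    import pandas as pd

    rows = []
    for gid, g in zip(graph_ids, graphs):
        kind = g.param.kind if g.param else ""
        pval = g.param.value if g.param else np.nan
        labels = g.labels or tuple(str(i) for i in range(g.n_nodes))
        for name in global_names:
            rows.append((gid, kind, pval, name, "global", "GLOBAL", GLOBAL_MEASURES[name](g)))
        for name in nodal_names:
            vec = NODAL_MEASURES[name](g)
            for lab, v in zip(labels, vec):
                rows.append((gid, kind, pval, name, "nodal", lab, float(v)))
    return pd.DataFrame(
        rows,
        columns=["graph", "param_kind", "param_value", "measure", "scope", "node", "value"],
    )
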